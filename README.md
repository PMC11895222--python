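# riskwba

Risk-based evaluation of binary classifiers, aimed at machine-learning
components of medical devices, where a false negative (a missed diagnosis)
and a false positive (a false alarm) rarely carry the same clinical cost.
The package is for developers and evaluators of such classifiers who need
to move from accuracy-style metrics to cost-weighted ones, pick decision
thresholds accordingly, and connect the result to an ISO-14971-style risk
matrix.

## The model and metrics

A thresholded classifier predicts positive when its score exceeds a
decision threshold *s*. With per-error costs *w*<sub>FP</sub>,
*w*<sub>FN</sub> (correct classifications cost nothing) and a cohort of
*P* actual positives and *N* actual negatives, the expected risk is

> ER(s) = *w*<sub>FP</sub>·N·FPR(s) + *w*<sub>FN</sub>·P·FNR(s)

Dividing by *w*<sub>FP</sub>·N leaves a single scalar in charge, the
**risk ratio** *c*<sub>FN</sub> = (*w*<sub>FN</sub>·P)/(*w*<sub>FP</sub>·N):

> ER̃(s) = FPR(s) + *c*<sub>FN</sub>·FNR(s)

The affinely equivalent accuracy-style metric is the **weighted balanced
accuracy**

> WBA(s) = (1 + *c*<sub>FN</sub> − ER̃(s)) / (1 + *c*<sub>FN</sub>)
>        = (*c*<sub>FN</sub>·TPR(s) + TNR(s)) / (1 + *c*<sub>FN</sub>)

which reduces to balanced accuracy at *c*<sub>FN</sub> = 1; maximizing WBA
and minimizing ER̃ pick the same threshold
s\* = argmin<sub>s</sub> ER̃(s).

For simulation studies the error curves come from a closed-form
"modified Gaussian" model,
FPR(s) = (1−s)·exp(−s²/σ<sub>FP</sub>) and
FNR(s) = s·exp(−(1−s)²/σ<sub>FN</sub>), whose σ parameters sweep ROC
curves from excellent (σ = 0.1) to mediocre (σ = 0.4) classifiers.
Empirical score/label files plug into the same metrics through step error
curves. A risk-matrix module maps (probability, severity) pairs to
acceptable / ALARP / unacceptable zones and converts hazard-to-harm
chains and multi-stratum risks into the cost weights above.

## Worked example

How much does it cost to keep the unweighted threshold when false
negatives are actually ten times worse? For the σ = 0.3 model:

```sh
$ riskwba sweep --sigmas 0.3 --cfns 1 --cfns 10
sigma_fp=0.3 / sigma_fn=0.3
    c_fn    s_opt   er_opt  er_default  rel_diff
    1.00     0.50     0.43        0.43      1.00
   10.00     0.16     0.92        2.39      2.59
```

At *c*<sub>FN</sub> = 1 the optimum sits at s = 0.5 with ER̃ = 0.43.
At *c*<sub>FN</sub> = 10 the optimum moves down to s = 0.16 (calling more
cases positive to avoid costly misses, ER̃ = 0.92) — but a device left at
the default threshold 0.5 operates at ER̃ = 2.39, a 2.59-fold (159 %)
higher expected risk. Across the swept models the penalty reaches 2.96
(196 %) at σ = 0.4, *c*<sub>FN</sub> = 10.

The same applies to real classifier outputs:

```sh
riskwba simulate --seed 5 --n-pos 200 --n-neg 200 --out preds.csv
riskwba evaluate --predictions preds.csv --wfp 1 --wfn 10
```

which derives *c*<sub>FN</sub> from the costs and the observed class
counts, reports metrics at the risk-optimal and the unweighted thresholds,
and the relative ER̃ difference between them. In Python the same is
`riskwba.evaluate_pipeline(scores, labels, RiskWeights(1, 10))`.

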