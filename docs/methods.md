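# Methods

## Error model

The simulation core represents a thresholded binary classifier by
closed-form error-rate curves over the decision threshold s ∈ [0, 1]:

    FPR(s) = (1 − s) · exp(−s² / σ_FP)
    FNR(s) = s · exp(−(1 − s)² / σ_FN)

The polynomial prefactors pin FPR(1) = FNR(0) = 0; both curves are smooth
and strictly monotone, so the induced ROC curves are proper and
differentiable. σ_FP and σ_FN (dimensionless, > 0) set how fast the error
rates decay; the study uses equal pairs σ ∈ {0.1, 0.2, 0.3, 0.4}, spanning
AUROC ≈ 0.99 down to ≈ 0.80. Equal σ makes the model mirror symmetric,
FPR(s) = FNR(1 − s), which is why the unweighted optimum sits at s = 0.5
and why the default-threshold penalty is symmetric under inversion of the
risk ratio.

## Risk-weighted metrics

Costs w_FP and w_FN (arbitrary but common units) are attached to the two
error types; correct classifications carry zero cost. With P positives
and N negatives, ER(s) = w_FP·N·FPR + w_FN·P·FNR; the normalized form
ER̃ = FPR + c_FN·FNR with c_FN = (w_FN·P)/(w_FP·N) is the same decision
problem (positive affine transforms preserve argmins). WBA is defined by
the affine mirror WBA = (1 + c_FN − ER̃)/(1 + c_FN); expanded in rates
this is (c_FN·TPR + TNR)/(1 + c_FN) — the sensitivity carries the risk
ratio, so costly false negatives up-weight TPR. (Some published
statements of the expanded form swap the TPR/TNR labels; the swapped
version breaks the affine identity and is not used here.) At c_FN = 1,
WBA = BA exactly.

Undefined ratios in the standard metrics (PPV with nothing predicted
positive, etc.) are reported as NaN, never 0; MCC uses the
product-of-rates form and agrees with the covariance form whenever all
four marginals are non-empty. Weighted kappa takes a 2×2 agreement-weight
table normalized so the diagonal weight is 1; the identity table gives
unweighted kappa.

## Threshold optimization and discretization

`optimize_threshold` evaluates ER̃ on the sampled grid and, for
parametric curves, refines inside the bracketing cell with a bounded
scalar search (tolerance 1e-10 in s); ties within 1e-12 in ER̃ resolve to
the smallest threshold. Empirical step curves take the plain grid argmin.
The default threshold in `relative_difference` is the argmin at c_FN = 1,
not a hard-coded 0.5, so asymmetric models are handled consistently.

The *sweep* (`experiments.run_sweep`) deliberately stays on a uniform
grid of step 0.02 without sub-grid refinement: every threshold reported by
the reference study is a multiple of 0.02, and reproducing its tabulated
values at two decimals requires evaluating on that grid (a fine grid with
refinement shifts several cells by one unit in the second decimal, e.g.
s_opt 0.155 → "0.15" instead of 0.16 at σ = 0.3, c_FN = 10). One cell is
irreconcilable either way: at σ = 0.1, c_FN = 16 the grid ratio is
2.574996 (→ 2.57) while the reference prints 2.58, which matches the
continuum optimum (2.5753) instead; the corresponding regression test
documents this and fails on exactly that cell. Reported values round half
away from zero to 2 decimals. The reference study's abstract quotes the
σ = 0.4, c_FN = 10 penalty as a 196 % relative increase (ratio 2.96); a
later passage says 198 % for the same quantity — 196 % is the value
consistent with the tabulated ratio.

In ROC space the optimum is where the curve touches a WBA iso-contour.
With the affine-consistent WBA the iso-contours are the lines
FPR = c_FN·TPR + const, so the first-order condition at an interior
optimum is dFPR/dTPR = c_FN (equivalently dTPR/dFPR = 1/c_FN).
`tangent_slope_check` verifies this with central differences (default
step 1e-5) and flags boundary optima (e.g. σ = 0.4, c_FN = 16, where the
argmin sits at s = 0) instead of differentiating across the edge.

## Risk matrix

Probability-of-harm levels follow the decade ladder frequent ≥ 1e-3,
probable ≥ 1e-4, occasional ≥ 1e-5, remote ≥ 1e-6, improbable < 1e-6
(the source table prints the lowest band as "< 1e-3", which contradicts
the band above it; < 1e-6 is the only consistent reading). Bands are
half-open with the stated bound inclusive. Severities are qualitative
levels with a multiplicative default weight step of 10 per level, chosen
so that one diagonal step in the matrix (probability down a decade,
severity up a level) leaves the combined risk probability × severity
constant. The default zone policy rates a cell by the sum of its
probability rank (improbable = 0 … frequent = 4) and severity rank
(negligible = 0 … catastrophic = 4): ≤ 3 acceptable, 4–5 ALARP, ≥ 6
unacceptable. This is a placeholder policy — the standard leaves the
assignment to the device's risk-management plan — and the whole map is
configurable via YAML.

Errors are hazardous situations, not harms: harm follows with a
conditional probability p₂, which `chain_hazard_to_harm` absorbs into the
cost weight (effective weight p₂·w). Multiple (probability, severity)
strata for one error type sum into a single effective weight
(`aggregate_weight`); risk contributions are additive, so this is
equivalent to summing per-stratum ER̃ terms.

## Synthetic scores and the empirical pipeline

The score generator is binormal: positives ~ N(μ_pos, σ_pos), negatives
~ N(μ_neg, σ_neg), with closed-form
AUROC = Φ((μ_pos − μ_neg)/√(σ_pos² + σ_neg²)) as an analytic oracle.
Defaults (μ_pos − μ_neg = 1 at unit spreads, AUROC ≈ 0.76) emulate a
moderately good clinical classifier; the stochastic regression tests use
10⁵ cases per class with fixed seeds and 3/√n tolerances. What the
generator does *not* emulate: non-Gaussian or heavy-tailed score
distributions, calibration drift, tied scores from quantized outputs, and
covariate-dependent error rates — passing tests therefore show metric and
optimizer correctness on well-behaved scores, not robustness to
real-world score pathologies.

Empirical curves use the convention *predict positive iff score ≥ t*,
thresholds at the sorted unique scores plus one sentinel above the
maximum. The pipeline derives c_FN from the cost weights and the
*observed* class counts (the evaluation should reflect the actual
prevalence); a target prevalence can override the composition when the
evaluation data were deliberately balanced. A perfectly separating
classifier has er_opt = 0; the default-threshold penalty is then reported
as an infinite-penalty flag rather than a ratio.

Clopper–Pearson one-sided upper bounds use the Beta-quantile identity
(Beta(k+1, n−k) quantile at 1 − α), with the closed form 1 − α^(1/n) at
zero successes. The bundled screening counts are 3/30, 1/30 and 0/27; the
1/30 bound computes to 0.149, which differs from the 0.16 quoted in the
source narrative (basis unclear) and is excluded from regression values.

## Known limitations

- Only two error costs; no costs for correct classifications and no
  multi-stage decision chains beyond the single hazard→harm factor.
- Benefits are not quantified; the framework prices risks only.
- The sweep's 0.02 grid is a reproduction choice; analyses that need
  threshold resolution below 0.02 should use `optimize_threshold` on a
  fine grid, which refines to ~1e-10.
- Empirical threshold optimization is exact only on the observed score
  set; no smoothing or interpolation between scores is attempted.
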