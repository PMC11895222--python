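"""Synthetic classifier scores, prediction-file I/O, and the evaluation pipeline.

The score generator is a binormal model: positive-class scores are drawn
from N(mu_pos, sd_pos) and negative-class scores from N(mu_neg, sd_neg).
Its closed-form AUROC,

    AUC = Phi((mu_pos - mu_neg) / sqrt(sd_pos^2 + sd_neg^2)),

serves as an analytic oracle for tests.  The defaults (unit separation at
unit spread, AUC ~ 0.76) emulate a moderately good clinical classifier.

:func:`evaluate_pipeline` composes the whole method on empirical scores:
build the step error curves, derive the risk ratio from the cost weights
and the observed class counts (the evaluation should reflect the actual
prevalence; a target prevalence can override the observed one), find the
risk-optimal and the unweighted-optimal thresholds, and report metrics and
the relative risk difference between the two operating points.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .error_model import ErrorCurves, empirical_curves
from .risk_metrics import (
    CohortComposition,
    ConfusionCounts,
    MetricReport,
    RiskWeights,
    risk_ratio,
    standard_metrics,
)
from .threshold_opt import ThresholdSolution, relative_difference

__all__ = [
    "BinormalScoreModel",
    "EvaluationResult",
    "binormal_scores",
    "binormal_auroc",
    "read_predictions",
    "write_predictions",
    "evaluate_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinormalScoreModel:
    """Binormal score generator (a stand-in for real classifier outputs)."""

    mu_pos: float = 1.0
    mu_neg: float = 0.0
    sd_pos: float = 1.0
    sd_neg: float = 1.0
    n_pos: int = 1000
    n_neg: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd_pos <= 0 or self.sd_neg <= 0:
            raise ValueError("score standard deviations must be positive")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("need at least one case per class")


def binormal_scores(model: BinormalScoreModel) -> tuple[np.ndarray, np.ndarray]:
    """Draw scores and 0/1 labels; deterministic for a given seed."""
    rng = np.random.default_rng(model.seed)
    pos = rng.normal(model.mu_pos, model.sd_pos, model.n_pos)
    neg = rng.normal(model.mu_neg, model.sd_neg, model.n_neg)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate(
        [np.ones(model.n_pos, dtype=int), np.zeros(model.n_neg, dtype=int)]
    )
    return scores, labels


def binormal_auroc(model: BinormalScoreModel) -> float:
    """Closed-form AUROC of the generating binormal model."""
    delta = model.mu_pos - model.mu_neg
    return float(norm.cdf(delta / math.hypot(model.sd_pos, model.sd_neg)))


def read_predictions(path, delimiter: str = ",") -> tuple[np.ndarray, np.ndarray]:
    """Load ``score,label`` predictions from a delimited text file.

    A header with ``score`` and ``label`` columns is required; labels must
    be 0/1.  Errors name the offending rows (1-based, excluding header).
    """
    try:
        frame = pd.read_csv(path, delimiter=delimiter, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty prediction file") from None
    missing = {"score", "label"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if len(frame) == 0:
        raise ValueError(f"{path}: no prediction rows")
    scores = pd.to_numeric(frame["score"], errors="coerce")
    bad = frame.index[scores.isna()] + 1
    if len(bad):
        raise ValueError(f"{path}: non-numeric score on rows {list(bad[:10])}")
    labels = pd.to_numeric(frame["label"], errors="coerce")
    bad = frame.index[~labels.isin([0, 1])] + 1
    if len(bad):
        raise ValueError(f"{path}: non-binary label on rows {list(bad[:10])}")
    return scores.to_numpy(dtype=float), labels.to_numpy(dtype=int)


def write_predictions(path, scores, labels, delimiter: str = ",") -> None:
    # %.17g guarantees binary round-trip of the scores through text
    pd.DataFrame({"score": scores, "label": labels}).to_csv(
        path, index=False, sep=delimiter, float_format="%.17g"
    )


def _confusion_at(scores, labels, threshold: float) -> ConfusionCounts:
    pred = scores >= threshold
    actual = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & actual)),
        fp=int(np.sum(pred & ~actual)),
        tn=int(np.sum(~pred & ~actual)),
        fn=int(np.sum(~pred & actual)),
    )


@dataclass(frozen=True)
class EvaluationResult:
    """End-to-end evaluation at the risk-optimal and default thresholds."""

    solution: ThresholdSolution
    metrics_at_opt: MetricReport
    metrics_at_default: MetricReport
    c_fn: float
    weights: RiskWeights
    cohort: CohortComposition

    def to_dict(self) -> dict:
        return {
            "c_fn": self.c_fn,
            "weights": dataclasses.asdict(self.weights),
            "cohort": dataclasses.asdict(self.cohort),
            "solution": self.solution.to_dict(),
            "metrics_at_opt": self.metrics_at_opt.to_dict(),
            "metrics_at_default": self.metrics_at_default.to_dict(),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def evaluate_pipeline(
    scores,
    labels,
    weights: RiskWeights,
    beta: float = 1.0,
    prevalence: float | None = None,
) -> EvaluationResult:
    """Risk-based evaluation of empirical classifier predictions.

    The risk ratio is derived from the cost weights and the observed class
    counts; passing a ``prevalence`` re-weights the composition to a
    target intended-use population (the observed total is kept).  Metrics
    are reported at the risk-optimal threshold and at the unweighted
    (``c_fn = 1``) optimum, together with the relative ER~ difference
    between the two operating points.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    curves = empirical_curves(scores, labels)

    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if prevalence is None:
        cohort = CohortComposition(p=n_pos, n=n_neg)
    else:
        if not 0.0 < prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        total = n_pos + n_neg
        cohort = CohortComposition(p=prevalence * total, n=(1 - prevalence) * total)
    c_fn = risk_ratio(weights, cohort)
    logger.info(
        "evaluate: n_pos=%d n_neg=%d prevalence=%.4g w_fp=%g w_fn=%g c_fn=%.4g",
        n_pos, n_neg, cohort.prevalence, weights.w_fp, weights.w_fn, c_fn,
    )
    logger.debug("curve grid: %d thresholds", len(curves))

    solution = relative_difference(curves, c_fn)
    metrics_opt = standard_metrics(
        _confusion_at(scores, labels, solution.s_opt), beta=beta, c_fn=c_fn
    )
    metrics_default = standard_metrics(
        _confusion_at(scores, labels, solution.s_default), beta=beta, c_fn=c_fn
    )
    logger.info(
        "thresholds: s_opt=%.6g s_default=%.6g relative_difference=%.4g",
        solution.s_opt, solution.s_default, solution.relative_difference,
    )
    return EvaluationResult(
        solution=solution,
        metrics_at_opt=metrics_opt,
        metrics_at_default=metrics_default,
        c_fn=c_fn,
        weights=weights,
        cohort=cohort,
    )
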