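"""Risk-weighted and standard performance metrics for binary classifiers.

The risk-weighted core assigns a cost ``w_fp`` to every false positive and
``w_fn`` to every false negative (correct classifications carry no cost).
For a cohort of P actual positives and N actual negatives at threshold s,

    ER(s)  = w_fp * N * FPR(s) + w_fn * P * FNR(s)

is the expected risk.  Dividing by ``w_fp * N`` gives the normalized form

    ER~(s) = FPR(s) + c_fn * FNR(s),   c_fn = (w_fn * P) / (w_fp * N),

so a single scalar, the *risk ratio* ``c_fn``, governs the trade-off between
the two error types.  The affinely equivalent accuracy-style metric is the
*weighted balanced accuracy*

    WBA(s) = (1 + c_fn - ER~(s)) / (1 + c_fn)
           = (c_fn * TPR(s) + TNR(s)) / (1 + c_fn),

which reduces to balanced accuracy at ``c_fn = 1`` and takes values in
[0, 1].  Maximizing WBA is therefore the same decision problem as
minimizing ER~.  Note the weight assignment: a costly false negative
(``c_fn > 1``) up-weights *sensitivity* (TPR), since
``1 - FNR = TPR`` carries the ``c_fn`` factor inherited from ER~.

Alongside these, :func:`standard_metrics` computes the conventional
point metrics (accuracy, F-scores, MCC, Cohen's kappa, ...) for
comparison.  Ratios with a zero denominator are reported as NaN, never as
0, so degenerate confusion tables cannot silently corrupt comparisons.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "CohortComposition",
    "RiskWeights",
    "MetricReport",
    "risk_ratio",
    "expected_risk",
    "normalized_expected_risk",
    "wba",
    "wba_weights",
    "standard_metrics",
    "aggregate_weight",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Raw confusion-table counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def p(self) -> int:
        """Actual positives P = TP + FN."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Actual negatives N = TN + FP."""
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class CohortComposition:
    """Actual class counts P (positives) and N (negatives)."""

    p: float
    n: float

    def __post_init__(self) -> None:
        if self.p < 0 or self.n < 0:
            raise ValueError("class counts must be non-negative")
        if self.p + self.n <= 0:
            raise ValueError("cohort must contain at least one case")

    @property
    def prevalence(self) -> float:
        return self.p / (self.p + self.n)


@dataclass(frozen=True)
class RiskWeights:
    """Costs per false positive and per false negative (same arbitrary units).

    The weights absorb both the severity of the associated harm and any
    hazard-to-harm transition probability (see :mod:`riskwba.risk_model`).
    """

    w_fp: float
    w_fn: float

    def __post_init__(self) -> None:
        if self.w_fp < 0 or self.w_fn < 0:
            raise ValueError("weights must be non-negative")
        if self.w_fp == 0 and self.w_fn == 0:
            raise ValueError("weights must not both be zero")

    @property
    def cost_ratio(self) -> float:
        """w_fn / w_fp; requires w_fp > 0."""
        if self.w_fp == 0:
            raise ZeroDivisionError("cost ratio undefined for w_fp = 0")
        return self.w_fn / self.w_fp


def risk_ratio(weights: RiskWeights, cohort: CohortComposition) -> float:
    """Risk ratio ``c_fn = (w_fn * P) / (w_fp * N)``."""
    denom = weights.w_fp * cohort.n
    if denom == 0:
        raise ZeroDivisionError(
            "risk ratio undefined: w_fp and N must both be positive"
        )
    return (weights.w_fn * cohort.p) / denom


def _check_rate(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{name} must lie in [0, 1]")


def expected_risk(
    fpr, fnr, weights: RiskWeights, cohort: CohortComposition
):
    """Expected risk ``w_fp * N * fpr + w_fn * P * fnr`` in cost units."""
    _check_rate("fpr", fpr)
    _check_rate("fnr", fnr)
    return weights.w_fp * cohort.n * fpr + weights.w_fn * cohort.p * fnr


def normalized_expected_risk(fpr, fnr, c_fn: float):
    """Normalized expected risk ``fpr + c_fn * fnr``.

    Equals ``expected_risk / (w_fp * N)``; scale-free and in
    [0, 1 + c_fn].
    """
    if not c_fn > 0:
        raise ValueError(f"c_fn must be positive, got {c_fn}")
    _check_rate("fpr", fpr)
    _check_rate("fnr", fnr)
    return fpr + c_fn * fnr


def wba_weights(c_fn: float) -> tuple[float, float]:
    """WBA convex weights ``(w_tp, w_tn) = (c_fn, 1) / (1 + c_fn)``.

    They sum to 1; the TPR weight carries the risk ratio so that WBA stays
    the affine mirror of the normalized expected risk.
    """
    if not c_fn > 0:
        raise ValueError(f"c_fn must be positive, got {c_fn}")
    return c_fn / (1.0 + c_fn), 1.0 / (1.0 + c_fn)


def wba(tpr, tnr, c_fn: float):
    """Weighted balanced accuracy ``(c_fn * tpr + tnr) / (1 + c_fn)``.

    Identically ``(1 + c_fn - ER~) / (1 + c_fn)`` for
    ``ER~ = (1 - tnr) + c_fn * (1 - tpr)``, so maximizing WBA and
    minimizing the normalized expected risk select the same threshold.
    """
    if not c_fn > 0:
        raise ValueError(f"c_fn must be positive, got {c_fn}")
    _check_rate("tpr", tpr)
    _check_rate("tnr", tnr)
    return (c_fn * tpr + tnr) / (1.0 + c_fn)


def aggregate_weight(strata: Iterable[tuple[float, float]]) -> float:
    """Sum probability x severity products into a single effective weight.

    When one error type carries several (probability, severity) strata in
    the risk analysis, their combined-risk contributions are additive and
    collapse into one cost weight.
    """
    total = 0.0
    for prob, severity in strata:
        if not 0.0 <= prob <= 1.0:
            raise ValueError(f"probability {prob} outside [0, 1]")
        if severity < 0:
            raise ValueError(f"severity weight {severity} negative")
        total += prob * severity
    return total


@dataclass(frozen=True)
class MetricReport:
    """Named point metrics of one confusion table.

    Ratios with a zero denominator are NaN.  ``wba`` and ``er_tilde`` are
    present only when a risk ratio was supplied to
    :func:`standard_metrics`.
    """

    tpr: float
    tnr: float
    acc: float
    err: float
    ba: float
    ppv: float
    npv: float
    f1: float
    fbeta: float
    beta: float
    mcc: float
    gmean: float
    kappa: float
    weighted_kappa: float
    wba: float = math.nan
    er_tilde: float = math.nan
    c_fn: float = math.nan

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_frame(self) -> pd.DataFrame:
        """One-row DataFrame, one metric per column (flat CSV layout)."""
        return pd.DataFrame([self.to_dict()])


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else math.nan


def standard_metrics(
    counts: ConfusionCounts,
    beta: float = 1.0,
    kappa_weights: Sequence[Sequence[float]] | None = None,
    c_fn: float | None = None,
) -> MetricReport:
    """Compute the full set of point metrics from confusion counts.

    Parameters
    ----------
    counts : ConfusionCounts
    beta : float
        Weight of recall vs precision in the F-beta score; must be > 0.
    kappa_weights : 2x2 array-like, optional
        Agreement weights for weighted Cohen's kappa, indexed
        ``[actual][predicted]`` with classes ordered (positive, negative).
        Normalized so the diagonal weight is 1; the identity table
        reproduces unweighted kappa.
    c_fn : float, optional
        Risk ratio; when given, WBA and the normalized expected risk are
        included in the report.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics for an all-zero confusion table")
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")

    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    p, n, tot = counts.p, counts.n, counts.total
    pp, pn = tp + fp, tn + fn  # predicted positive / negative

    tpr = _safe_div(tp, p)
    tnr = _safe_div(tn, n)
    ppv = _safe_div(tp, pp)
    npv = _safe_div(tn, pn)
    acc = (tp + tn) / tot
    ba = (tpr + tnr) / 2.0

    f1 = _safe_div(2.0 * ppv * tpr, ppv + tpr)
    b2 = beta * beta
    fbeta = _safe_div((1.0 + b2) * ppv * tpr, b2 * ppv + tpr)

    # MCC in the product-of-rates form; NaN whenever any marginal is empty
    if math.isnan(tpr) or math.isnan(tnr) or math.isnan(ppv) or math.isnan(npv):
        mcc = math.nan
    else:
        mcc = math.sqrt(tpr * tnr * ppv * npv) - math.sqrt(
            (1.0 - tpr) * (1.0 - tnr) * (1.0 - ppv) * (1.0 - npv)
        )
    gmean = (
        math.nan
        if math.isnan(tpr) or math.isnan(tnr)
        else math.sqrt(tpr * tnr)
    )

    kappa = _cohen_kappa(counts, weights=None)
    weighted_kappa = (
        _cohen_kappa(counts, weights=kappa_weights)
        if kappa_weights is not None
        else math.nan
    )

    extra: dict[str, float] = {}
    if c_fn is not None:
        if math.isnan(tpr) or math.isnan(tnr):
            extra = {"wba": math.nan, "er_tilde": math.nan, "c_fn": c_fn}
        else:
            extra = {
                "wba": wba(tpr, tnr, c_fn),
                "er_tilde": normalized_expected_risk(1.0 - tnr, 1.0 - tpr, c_fn),
                "c_fn": c_fn,
            }

    return MetricReport(
        tpr=tpr,
        tnr=tnr,
        acc=acc,
        err=1.0 - acc,
        ba=ba,
        ppv=ppv,
        npv=npv,
        f1=f1,
        fbeta=fbeta,
        beta=beta,
        mcc=mcc,
        gmean=gmean,
        kappa=kappa,
        weighted_kappa=weighted_kappa,
        **extra,
    )


def _cohen_kappa(
    counts: ConfusionCounts, weights: Sequence[Sequence[float]] | None
) -> float:
    """Cohen's kappa with optional 2x2 agreement weights.

    Observed table o[i][j] (i = actual, j = predicted; class order
    positive, negative) is compared against the chance table from the
    marginals.  With agreement weights v (diagonal normalized to 1),

        kappa_w = (po_w - pe_w) / (1 - pe_w),
        po_w = sum v o / tot,  pe_w = sum v e / tot.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    tot = counts.total
    o = np.array([[tp, fn], [fp, tn]], dtype=float)
    row = o.sum(axis=1)
    col = o.sum(axis=0)
    e = np.outer(row, col) / tot

    if weights is None:
        v = np.eye(2)
    else:
        v = np.asarray(weights, dtype=float)
        if v.shape != (2, 2):
            raise ValueError("kappa_weights must be a 2x2 table")
        if np.any(v < 0):
            raise ValueError("kappa weights must be non-negative")
        diag = np.diag(v)
        if np.any(diag <= 0):
            raise ValueError("diagonal kappa weights must be positive")
        v = v / diag.max()

    po = float((v * o).sum()) / tot
    pe = float((v * e).sum()) / tot
    if pe == 1.0:
        return math.nan
    return (po - pe) / (1.0 - pe)
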