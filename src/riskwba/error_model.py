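"""Error-rate curves of a thresholded binary classifier.

Two origins are supported:

* **Parametric**: closed-form "modified Gaussian" false-positive and
  false-negative rate curves over a decision threshold ``s`` in [0, 1],

  .. math::

      FPR(s) = (1 - s)\\,\\exp(-s^2/\\sigma_{FP}), \\qquad
      FNR(s) = s\\,\\exp(-(1 - s)^2/\\sigma_{FN}).

  The prefactors pin :math:`FPR(1) = FNR(0) = 0`, and the scale parameters
  :math:`\\sigma_{FP}, \\sigma_{FN} > 0` control how quickly each error rate
  decays, i.e. the quality of the emulated classifier.  For
  :math:`\\sigma_{FP} = \\sigma_{FN}` the model is mirror symmetric,
  :math:`FPR(s) = FNR(1 - s)`.

* **Empirical**: step curves computed from observed classifier scores and
  binary labels, under the convention *predict positive iff score >= t*.

Both are carried in the :class:`ErrorCurves` container, from which ROC
points and the AUROC are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ParametricErrorModel",
    "ErrorCurves",
    "parametric_fpr",
    "parametric_fnr",
    "sample_curves",
    "empirical_curves",
    "roc_points",
    "auroc",
]


@dataclass(frozen=True)
class ParametricErrorModel:
    """Shape parameters of the closed-form error curves.

    Parameters
    ----------
    sigma_fp, sigma_fn : float
        Positive, dimensionless scales of the FPR and FNR curves.  Smaller
        values push the ROC curve towards the ideal (0, 1) corner.
    """

    sigma_fp: float
    sigma_fn: float

    def __post_init__(self) -> None:
        if not (self.sigma_fp > 0 and self.sigma_fn > 0):
            raise ValueError(
                f"sigma_fp and sigma_fn must be positive, got "
                f"({self.sigma_fp}, {self.sigma_fn})"
            )

    def fpr(self, s):
        """False-positive rate at threshold(s) ``s``."""
        return parametric_fpr(s, self)

    def fnr(self, s):
        """False-negative rate at threshold(s) ``s``."""
        return parametric_fnr(s, self)


def _check_threshold_domain(s) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if np.any(s < 0.0) or np.any(s > 1.0):
        raise ValueError("threshold s must lie in [0, 1]")
    return s


def parametric_fpr(s, model: ParametricErrorModel):
    """Closed-form false-positive rate ``(1 - s) * exp(-s^2 / sigma_fp)``.

    Accepts scalars or arrays; raises ``ValueError`` outside [0, 1].
    Results are clamped into [0, 1] to guard against -0.0.
    """
    arr = _check_threshold_domain(s)
    out = np.clip((1.0 - arr) * np.exp(-(arr**2) / model.sigma_fp), 0.0, 1.0)
    return float(out) if np.isscalar(s) or np.ndim(s) == 0 else out


def parametric_fnr(s, model: ParametricErrorModel):
    """Closed-form false-negative rate ``s * exp(-(1 - s)^2 / sigma_fn)``."""
    arr = _check_threshold_domain(s)
    out = np.clip(arr * np.exp(-((1.0 - arr) ** 2) / model.sigma_fn), 0.0, 1.0)
    return float(out) if np.isscalar(s) or np.ndim(s) == 0 else out


@dataclass
class ErrorCurves:
    """FPR/FNR sampled on a threshold grid.

    Attributes
    ----------
    thresholds : ndarray
        Strictly increasing decision thresholds.  Within [0, 1] for
        parametric origin; arbitrary score values for empirical curves.
    fpr, fnr : ndarray
        Error rates at each threshold, in [0, 1].
    origin : {"parametric", "empirical"}
    model : ParametricErrorModel, optional
        The generating model, retained for parametric curves so that
        downstream optimizers can refine between grid points.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    fnr: np.ndarray
    origin: str
    model: ParametricErrorModel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.fnr = np.asarray(self.fnr, dtype=float)
        if not (self.thresholds.shape == self.fpr.shape == self.fnr.shape):
            raise ValueError("thresholds, fpr and fnr must have equal shape")
        if self.thresholds.size == 0:
            raise ValueError("curves must contain at least one threshold")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        for name, arr in (("fpr", self.fpr), ("fnr", self.fnr)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")
        if self.origin not in ("parametric", "empirical"):
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.origin == "parametric" and (
            self.thresholds[0] < 0 or self.thresholds[-1] > 1
        ):
            raise ValueError("parametric thresholds must lie in [0, 1]")

    def __len__(self) -> int:
        return self.thresholds.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "fnr": self.fnr}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sample_curves(model: ParametricErrorModel, n_grid: int = 10001) -> ErrorCurves:
    """Evaluate the parametric model on a uniform grid over [0, 1].

    ``n_grid`` points including both endpoints; ``n_grid >= 2`` required.
    """
    if n_grid < 2:
        raise ValueError(f"n_grid must be >= 2, got {n_grid}")
    s = np.linspace(0.0, 1.0, int(n_grid))
    return ErrorCurves(
        thresholds=s,
        fpr=parametric_fpr(s, model),
        fnr=parametric_fnr(s, model),
        origin="parametric",
        model=model,
    )


def empirical_curves(scores, labels) -> ErrorCurves:
    """Step error curves from observed scores and 0/1 labels.

    Thresholds are the sorted unique scores plus one sentinel above the
    maximum (the predict-nothing-positive operating point).  At threshold
    ``t`` a case is predicted positive iff its score >= ``t``, so
    ``fpr = #\\{negatives with score >= t\\} / N`` and
    ``fnr = #\\{positives with score < t\\} / P``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.ndim != 1 or labels.ndim != 1 or scores.size != labels.size:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if scores.size == 0:
        raise ValueError("empty input")
    uniq = np.unique(labels)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError(f"labels must be binary 0/1, found values {uniq}")
    if uniq.size < 2:
        raise ValueError("both classes must be present to form error curves")

    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    n_pos, n_neg = pos.size, neg.size

    thresholds = np.unique(scores)
    # sentinel strictly above every observed score: nothing predicted positive
    span = thresholds[-1] - thresholds[0]
    sentinel = thresholds[-1] + (span if span > 0 else 1.0) * 1e-3 + 1e-12
    thresholds = np.append(thresholds, sentinel)

    # FP: negatives with score >= t ; FN: positives with score < t
    fp = n_neg - np.searchsorted(neg, thresholds, side="left")
    fn = np.searchsorted(pos, thresholds, side="left")
    return ErrorCurves(
        thresholds=thresholds,
        fpr=fp / n_neg,
        fnr=fn / n_pos,
        origin="empirical",
    )


def roc_points(curves: ErrorCurves) -> pd.DataFrame:
    """ROC representation ``(fpr, tpr)`` with threshold correspondence.

    Returns a DataFrame with columns ``fpr``, ``tpr`` (= 1 - fnr) and
    ``threshold``, sorted by ascending ``fpr``.
    """
    frame = pd.DataFrame(
        {
            "fpr": curves.fpr,
            "tpr": 1.0 - curves.fnr,
            "threshold": curves.thresholds,
        }
    )
    return frame.sort_values(["fpr", "tpr"], kind="mergesort").reset_index(drop=True)


def auroc(curves: ErrorCurves) -> float:
    """Area under the ROC curve by the trapezoid rule.

    Points are sorted by FPR; ties in FPR are resolved by keeping the
    maximum TPR (the step-curve limit of the integral definition).
    """
    pts = roc_points(curves)
    collapsed = pts.groupby("fpr", sort=True)["tpr"].max()
    x = collapsed.index.to_numpy()
    y = collapsed.to_numpy()
    if x.size < 2:
        raise ValueError("need at least 2 distinct FPR values to integrate")
    return float(np.trapezoid(y, x))
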