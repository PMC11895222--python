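"""Risk-optimal threshold selection and the cost of ignoring risk weights.

The decision problem is ``s* = argmin_s ER~(s) = FPR(s) + c_fn * FNR(s)``.
For sampled parametric curves the grid argmin is refined by a bounded
scalar search inside the bracketing grid cell; empirical step curves have
no interior smoothness, so the plain grid argmin is returned.

The headline diagnostic is the *relative difference*: how much larger the
weighted expected risk gets when the threshold tuned for the unweighted
problem (``c_fn = 1``) is kept, instead of re-optimizing for the true risk
ratio.  In ROC space the optimum is where the curve is tangent to a WBA
iso-contour, whose slope is exactly ``c_fn``;
:func:`tangent_slope_check` verifies this first-order condition.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .error_model import ErrorCurves, parametric_fnr, parametric_fpr
from .risk_metrics import normalized_expected_risk

__all__ = [
    "ThresholdSolution",
    "TangentDiagnostic",
    "optimize_threshold",
    "relative_difference",
    "tangent_slope_check",
    "round_half_away",
]

#: thresholds whose ER~ is within this of the minimum count as ties
_TIE_TOL = 1e-12


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (presentation rounding for reports)."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


@dataclass(frozen=True)
class ThresholdSolution:
    """Optimal threshold and the penalty of the unweighted default.

    ``relative_difference`` is ``er_default_weighted / er_opt`` (>= 1);
    ``inf`` flags the degenerate case ``er_opt = 0 < er_default_weighted``.
    """

    s_opt: float
    er_opt: float
    s_default: float
    er_default_weighted: float
    relative_difference: float
    c_fn: float

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def _er_on_grid(curves: ErrorCurves, c_fn: float) -> np.ndarray:
    return normalized_expected_risk(curves.fpr, curves.fnr, c_fn)


def _er_exact(curves: ErrorCurves, c_fn: float, s: float) -> float:
    """ER~ at an arbitrary threshold: closed form when the model is known,
    otherwise the step-curve value at the nearest grid threshold."""
    if curves.model is not None:
        return float(
            normalized_expected_risk(
                parametric_fpr(s, curves.model),
                parametric_fnr(s, curves.model),
                c_fn,
            )
        )
    idx = int(np.argmin(np.abs(curves.thresholds - s)))
    return float(_er_on_grid(curves, c_fn)[idx])


def optimize_threshold(
    curves: ErrorCurves, c_fn: float, refine: bool | None = None
) -> tuple[float, float]:
    """Global minimizer of ``ER~(s)`` over the curve's thresholds.

    Parameters
    ----------
    curves : ErrorCurves
    c_fn : float
        Positive risk ratio.
    refine : bool, optional
        Refine the grid argmin by a bounded golden/parabolic search in the
        bracketing cell.  Defaults to True for parametric curves with a
        retained model, False otherwise.

    Returns
    -------
    (s_opt, er_opt)
        Ties within 1e-12 in ER~ resolve to the smallest threshold.
    """
    if not c_fn > 0:
        raise ValueError(f"c_fn must be positive, got {c_fn}")
    if len(curves) == 0:
        raise ValueError("empty curves")
    er = _er_on_grid(curves, c_fn)
    # smallest threshold among near-ties at the minimum
    i = int(np.flatnonzero(er <= er.min() + _TIE_TOL)[0])
    s_opt = float(curves.thresholds[i])
    er_opt = float(er[i])

    if refine is None:
        refine = curves.model is not None
    if refine and curves.model is not None and len(curves) > 2:
        lo = float(curves.thresholds[max(i - 1, 0)])
        hi = float(curves.thresholds[min(i + 1, len(curves) - 1)])
        model = curves.model
        res = minimize_scalar(
            lambda s: normalized_expected_risk(
                parametric_fpr(s, model), parametric_fnr(s, model), c_fn
            ),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun <= er_opt:
            s_opt, er_opt = float(res.x), float(res.fun)
    return s_opt, er_opt


def relative_difference(
    curves: ErrorCurves,
    c_fn: float,
    s_default: float | None = None,
    refine: bool | None = None,
) -> ThresholdSolution:
    """Penalty of operating at the unweighted-optimal threshold.

    ``s_default`` defaults to the argmin at ``c_fn = 1`` (0.5 only for
    mirror-symmetric models).  ER~ with the *true* ``c_fn`` is evaluated at
    both thresholds; their ratio quantifies the cost of ignoring the risk
    weighting.
    """
    if s_default is None:
        s_default, _ = optimize_threshold(curves, 1.0, refine=refine)
    else:
        lo, hi = curves.thresholds[0], curves.thresholds[-1]
        if not (lo <= s_default <= hi):
            raise ValueError(
                f"s_default {s_default} outside curve range [{lo}, {hi}]"
            )
    s_opt, er_opt = optimize_threshold(curves, c_fn, refine=refine)
    er_default = _er_exact(curves, c_fn, s_default)
    if er_opt > 0:
        ratio = er_default / er_opt
    elif er_default > 0:
        ratio = math.inf  # infinite-penalty flag
    else:
        ratio = 1.0
    return ThresholdSolution(
        s_opt=s_opt,
        er_opt=er_opt,
        s_default=float(s_default),
        er_default_weighted=er_default,
        relative_difference=ratio,
        c_fn=c_fn,
    )


@dataclass(frozen=True)
class TangentDiagnostic:
    """First-order optimality check in ROC space.

    WBA iso-contours are the straight lines ``FPR = c_fn * TPR + const``,
    so at an interior optimum the ROC curve satisfies
    ``dFPR/dTPR = c_fn`` (equivalently ``dTPR/dFPR = 1/c_fn``).
    ``roc_slope`` reports the finite-difference ``dFPR/dTPR`` and ``gap``
    its distance to ``iso_slope = c_fn``.  ``boundary`` flags optima at
    (or within one finite-difference step of) the domain edge, where the
    check is skipped.
    """

    roc_slope: float
    iso_slope: float
    gap: float
    boundary: bool

    def within(self, tol: float) -> bool:
        return not self.boundary and self.gap <= tol


def tangent_slope_check(
    curves: ErrorCurves, c_fn: float, s_opt: float, fd_step: float = 1e-5
) -> TangentDiagnostic:
    """Compare the finite-difference ROC slope at ``s_opt`` with ``c_fn``.

    Requires a differentiable (parametric) curve; by the chain rule
    ``dFPR/dTPR = FPR'(s) / (-FNR'(s))``, computed with central
    differences of step ``fd_step``.
    """
    if curves.model is None:
        raise ValueError("tangent check requires a parametric curve with model")
    if s_opt - fd_step < 0.0 or s_opt + fd_step > 1.0:
        return TangentDiagnostic(
            roc_slope=math.nan, iso_slope=c_fn, gap=math.nan, boundary=True
        )
    model = curves.model
    dfpr = (
        parametric_fpr(s_opt + fd_step, model) - parametric_fpr(s_opt - fd_step, model)
    ) / (2 * fd_step)
    dfnr = (
        parametric_fnr(s_opt + fd_step, model) - parametric_fnr(s_opt - fd_step, model)
    ) / (2 * fd_step)
    roc_slope = dfpr / (-dfnr)  # dFPR/dTPR, since dTPR = -dFNR
    return TangentDiagnostic(
        roc_slope=float(roc_slope),
        iso_slope=c_fn,
        gap=abs(float(roc_slope) - c_fn),
        boundary=False,
    )
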