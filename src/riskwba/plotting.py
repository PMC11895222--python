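"""Optional diagnostic plots (requires matplotlib).

Never imported by the core modules or required by tests.
"""

from __future__ import annotations

import numpy as np

from .error_model import ErrorCurves, roc_points
from .risk_metrics import normalized_expected_risk, wba

__all__ = ["plot_expected_risk", "plot_roc_with_wba"]


def plot_expected_risk(curves: ErrorCurves, c_values, ax=None):
    """ER~(s) against the threshold for several risk ratios, with the
    minimum of each curve marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in c_values:
        er = normalized_expected_risk(curves.fpr, curves.fnr, c)
        ax.plot(curves.thresholds, er, label=f"$c_{{FN}}={c:g}$")
        i = int(np.argmin(er))
        ax.plot(curves.thresholds[i], er[i], "k|", markersize=10)
    ax.axvline(0.5, linestyle="--", color="grey", linewidth=0.8)
    ax.set_xlabel("threshold $s$")
    ax.set_ylabel(r"$\widetilde{ER}(s)$")
    ax.legend()
    return ax


def plot_roc_with_wba(curves: ErrorCurves, c_fn: float, ax=None, levels: int = 11):
    """ROC curve over the WBA colour field with its straight iso-contours
    (slope c_fn); the tangent point is the risk-optimal operating point."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(0.0, 1.0, 201)
    fpr_g, tpr_g = np.meshgrid(grid, grid)
    field = wba(tpr_g, 1.0 - fpr_g, c_fn)
    ax.pcolormesh(grid, grid, field, shading="auto", cmap="viridis")
    ax.contour(grid, grid, field, levels=levels, colors="w", linewidths=0.5)
    pts = roc_points(curves)
    ax.plot(pts["fpr"], pts["tpr"], "r-", linewidth=2)
    ax.plot([0, 1], [0, 1], "k--", linewidth=0.8)
    ax.set_xlabel("FPR")
    ax.set_ylabel("TPR")
    ax.set_title(f"ROC with WBA iso-contours, $c_{{FN}}={c_fn:g}$")
    return ax
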