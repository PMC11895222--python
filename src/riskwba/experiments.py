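"""The closed-form simulation study and exact binomial confidence bounds.

:func:`run_sweep` varies the risk ratio ``c_fn`` over a logarithmic ladder
(2^-4 ... 2^4 by factors of 2, plus the risk-matrix reference points 0.1
and 10.0) for a family of mirror-symmetric modified-Gaussian error models
(sigma = 0.1 ... 0.4), and records for each cell the risk-optimal
threshold, the normalized expected risk there, the risk at the unweighted
default threshold, and their ratio.  Everything is deterministic and
seedless -- the error model is closed form.

The study evaluates thresholds on a uniform grid of step 0.02 (every
reported optimum is a multiple of 0.02); the step is configurable for
sensitivity checks.

:func:`clopper_upper` gives the one-sided exact (Clopper-Pearson) upper
binomial confidence bound used for the literature-screening rates, whose
observed counts ship as :data:`LITERATURE_COUNTS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .error_model import ParametricErrorModel, sample_curves
from .threshold_opt import optimize_threshold, relative_difference, round_half_away

__all__ = [
    "SweepResult",
    "run_sweep",
    "table3_report",
    "clopper_upper",
    "DEFAULT_SIGMAS",
    "DEFAULT_C_VALUES",
    "LITERATURE_COUNTS",
]

#: equal-sigma model family spanning poor-to-good classifiers
DEFAULT_SIGMAS: tuple[tuple[float, float], ...] = (
    (0.1, 0.1),
    (0.2, 0.2),
    (0.3, 0.3),
    (0.4, 0.4),
)

#: risk-ratio ladder 2^-4 .. 2^4 plus the one-risk-matrix-level points
DEFAULT_C_VALUES: tuple[float, ...] = tuple(
    sorted({2.0**k for k in range(-4, 5)} | {0.1, 10.0})
)

#: literature-screening outcomes (successes, n): C1 risk-related papers,
#: C2 papers with risk-weighted evaluation, C3 restricted to
#: non-risk-prediction use cases
LITERATURE_COUNTS: dict[str, tuple[int, int]] = {
    "C1": (3, 30),
    "C2": (1, 30),
    "C3": (0, 27),
}

#: threshold grid step of the simulation study
STUDY_GRID_STEP = 0.02

_COLUMNS = [
    "sigma_fp",
    "sigma_fn",
    "c_fn",
    "s_opt",
    "er_opt",
    "er_default",
    "relative_difference",
]


@dataclass
class SweepResult:
    """Sweep rows plus grid provenance (fully deterministic)."""

    table: pd.DataFrame
    grid_step: float
    s_default: dict[tuple[float, float], float] = field(default_factory=dict)

    def block(self, sigma_fp: float, sigma_fn: float) -> pd.DataFrame:
        t = self.table
        return t[(t.sigma_fp == sigma_fp) & (t.sigma_fn == sigma_fn)]

    def cell(self, sigma: float, c_fn: float) -> pd.Series:
        """Row for an equal-sigma model at one risk ratio."""
        t = self.table
        rows = t[
            (t.sigma_fp == sigma) & (t.sigma_fn == sigma) & (t.c_fn == c_fn)
        ]
        if rows.empty:
            raise KeyError(f"no sweep row for sigma={sigma}, c_fn={c_fn}")
        return rows.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_sweep(
    sigmas: Sequence[tuple[float, float]] | None = None,
    c_values: Sequence[float] | None = None,
    grid_step: float = STUDY_GRID_STEP,
) -> SweepResult:
    """Threshold-optimization sweep over model parameters and risk ratios.

    For each sigma pair the default threshold is the grid argmin of ER~ at
    ``c_fn = 1``; each row then reports the re-optimized threshold and the
    relative difference in ER~ between default and optimum at the true
    ``c_fn``.  Thresholds stay on the evaluation grid (no sub-grid
    refinement), matching the study's discretization.
    """
    sigmas = tuple(DEFAULT_SIGMAS if sigmas is None else sigmas)
    c_values = tuple(DEFAULT_C_VALUES if c_values is None else c_values)
    if not sigmas or not c_values:
        raise ValueError("sigmas and c_values must be non-empty")
    if not 0 < grid_step <= 0.5:
        raise ValueError(f"grid_step must lie in (0, 0.5], got {grid_step}")
    n_grid = int(round(1.0 / grid_step)) + 1

    rows = []
    s_defaults: dict[tuple[float, float], float] = {}
    for sigma_fp, sigma_fn in sigmas:
        model = ParametricErrorModel(sigma_fp=sigma_fp, sigma_fn=sigma_fn)
        curves = sample_curves(model, n_grid=n_grid)
        s_default, _ = optimize_threshold(curves, 1.0, refine=False)
        s_defaults[(sigma_fp, sigma_fn)] = s_default
        for c in c_values:
            if not c > 0:
                raise ValueError(f"risk ratios must be positive, got {c}")
            sol = relative_difference(curves, c, s_default=s_default, refine=False)
            rows.append(
                {
                    "sigma_fp": sigma_fp,
                    "sigma_fn": sigma_fn,
                    "c_fn": c,
                    "s_opt": sol.s_opt,
                    "er_opt": sol.er_opt,
                    "er_default": sol.er_default_weighted,
                    "relative_difference": sol.relative_difference,
                }
            )
    return SweepResult(
        table=pd.DataFrame(rows, columns=_COLUMNS),
        grid_step=grid_step,
        s_default=s_defaults,
    )


def table3_report(result: SweepResult, ndigits: int = 2) -> str:
    """Render the sweep as the study's presentation table.

    Columns: risk ratio, optimal threshold, ER~ at the optimum, ER~ at the
    default threshold, relative difference; values rounded half away from
    zero to ``ndigits``.  One block per sigma pair.
    """
    lines = []
    header = f"{'c_fn':>8} {'s_opt':>8} {'er_opt':>8} {'er_default':>11} {'rel_diff':>9}"
    if result.table.empty:
        return header + "\n"
    for (sfp, sfn), block in result.table.groupby(
        ["sigma_fp", "sigma_fn"], sort=True
    ):
        lines.append(f"sigma_fp={sfp} / sigma_fn={sfn}")
        lines.append(header)
        for _, row in block.iterrows():
            lines.append(
                f"{round_half_away(row.c_fn, ndigits):>8.2f} "
                f"{round_half_away(row.s_opt, ndigits):>8.2f} "
                f"{round_half_away(row.er_opt, ndigits):>8.2f} "
                f"{round_half_away(row.er_default, ndigits):>11.2f} "
                f"{round_half_away(row.relative_difference, ndigits):>9.2f}"
            )
        lines.append("")
    return "\n".join(lines)


def clopper_upper(successes: int, n: int, alpha: float = 0.05) -> float:
    """One-sided exact (Clopper-Pearson) upper confidence bound.

    The bound is the ``p`` solving ``P(X <= successes | n, p) = alpha``,
    i.e. the ``1 - alpha`` quantile of Beta(successes + 1, n - successes);
    ``successes = n`` returns 1.  For zero successes this reduces to the
    closed form ``1 - alpha ** (1/n)``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, {n}], got {successes}")
    if successes == n:
        return 1.0
    return float(beta_dist.ppf(1.0 - alpha, successes + 1, n - successes))
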