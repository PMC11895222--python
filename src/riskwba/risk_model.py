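"""Semi-quantitative risk categorization and the risk-matrix mapping.

Risk, in the ISO-14971 sense, combines a probability (likelihood of harm
per use) with a severity level.  Probability levels follow the usual
decade ladder (frequent >= 1e-3, probable >= 1e-4, occasional >= 1e-5,
remote >= 1e-6, improbable < 1e-6) and severities a qualitative scale from
negligible to catastrophic.  With a multiplicative combination rule and a
decade step between severity levels, one diagonal step in the matrix
(probability down one level, severity up one) leaves the combined risk
approximately constant.

Each (probability level, severity level) cell belongs to an acceptability
zone -- ``acceptable``, ``alarp`` ("as low as reasonably practicable":
needs further investigation) or ``unacceptable`` (must be reduced).  The
exact cell-to-zone assignment is a policy choice that must be fixed in the
risk-management plan; :func:`default_spec` supplies a documented default
and the whole map is configurable (YAML).

The module also links the matrix back to the classifier-evaluation core:
:func:`balanced_composition` inverts the risk ratio
``c_fn = (w_fn / w_fp) * (P / N)`` for the class composition that realizes
a target overall ratio, and :func:`chain_hazard_to_harm` absorbs the
hazard-to-harm transition probability into an error-cost weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

__all__ = [
    "ProbabilityLevel",
    "RiskMatrixSpec",
    "RiskEntry",
    "default_spec",
    "probability_level",
    "classify_risk",
    "combined_risk",
    "balanced_composition",
    "chain_hazard_to_harm",
    "read_register",
    "write_register",
]

ZONES = ("acceptable", "alarp", "unacceptable")


@dataclass(frozen=True)
class ProbabilityLevel:
    """Named probability band ``[lower, upper_of_previous)``."""

    name: str
    lower: float  # inclusive lower bound of the band, 0 for the lowest


@dataclass
class RiskMatrixSpec:
    """Probability/severity level scheme with an acceptability-zone map.

    ``probability_levels`` are ordered from most to least likely with
    strictly decreasing lower bounds; ``severity_levels`` from least to
    most severe.  ``severity_step`` is the multiplicative weight increment
    between adjacent severity levels (default one decade).  ``zone_map``
    must cover the full level grid.
    """

    probability_levels: list[ProbabilityLevel]
    severity_levels: list[str]
    zone_map: dict[tuple[str, str], str]
    severity_step: float = 10.0

    def __post_init__(self) -> None:
        lowers = [lvl.lower for lvl in self.probability_levels]
        if any(b >= a for a, b in zip(lowers, lowers[1:])):
            raise ValueError("probability lower bounds must be strictly decreasing")
        if lowers and (lowers[0] > 1.0 or any(b < 0 for b in lowers)):
            raise ValueError("probability bounds must lie in [0, 1]")
        if self.severity_step <= 0:
            raise ValueError("severity_step must be positive")
        grid = {
            (p.name, s) for p in self.probability_levels for s in self.severity_levels
        }
        missing = grid - set(self.zone_map)
        if missing:
            raise ValueError(f"zone_map does not cover cells: {sorted(missing)}")
        bad = {z for z in self.zone_map.values() if z not in ZONES}
        if bad:
            raise ValueError(f"unknown zones {sorted(bad)}; expected one of {ZONES}")

    def severity_weight(self, severity_index: int) -> float:
        """Multiplicative weight ``severity_step ** index`` of a level."""
        if not 0 <= severity_index < len(self.severity_levels):
            raise IndexError(f"severity index {severity_index} outside grid")
        return self.severity_step**severity_index

    @classmethod
    def from_config(cls, path) -> "RiskMatrixSpec":
        """Load a spec from a YAML config.

        Expected keys: ``probability_levels`` (name -> lower bound, in
        order), ``severity_levels`` (list), optional ``severity_step``,
        and ``zones`` (probability level -> severity level -> zone).
        """
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        plevels = [
            ProbabilityLevel(name, float(lower))
            for name, lower in cfg["probability_levels"].items()
        ]
        slevels = list(cfg["severity_levels"])
        zone_map = {
            (p, s): zone
            for p, row in cfg["zones"].items()
            for s, zone in row.items()
        }
        return cls(
            probability_levels=plevels,
            severity_levels=slevels,
            zone_map=zone_map,
            severity_step=float(cfg.get("severity_step", 10.0)),
        )

    def to_config(self, path) -> None:
        cfg = {
            "probability_levels": {p.name: p.lower for p in self.probability_levels},
            "severity_levels": list(self.severity_levels),
            "severity_step": self.severity_step,
            "zones": {
                p.name: {
                    s: self.zone_map[(p.name, s)] for s in self.severity_levels
                }
                for p in self.probability_levels
            },
        }
        Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def default_spec() -> RiskMatrixSpec:
    """The bundled default: decade probability ladder, five severities.

    The printed source of the ladder lists the lowest band inconsistently
    (``improbable: < 1e-3``); the only internally consistent reading,
    ``< 1e-6``, is used.  Zones follow a rank-sum policy: with probability
    ranks improbable=0..frequent=4 and severity ranks negligible=0..
    catastrophic=4, a cell is acceptable for rank sum <= 3, ALARP for 4-5
    (the one-off diagonal band) and unacceptable for >= 6.
    """
    plevels = [
        ProbabilityLevel("frequent", 1e-3),
        ProbabilityLevel("probable", 1e-4),
        ProbabilityLevel("occasional", 1e-5),
        ProbabilityLevel("remote", 1e-6),
        ProbabilityLevel("improbable", 0.0),
    ]
    slevels = ["negligible", "minor", "serious", "critical", "catastrophic"]
    n_p = len(plevels)
    zone_map = {}
    for p_rank, p in enumerate(plevels):  # frequent first -> rank n_p-1-i
        for s_rank, s in enumerate(slevels):
            score = (n_p - 1 - p_rank) + s_rank
            if score <= 3:
                zone = "acceptable"
            elif score <= 5:
                zone = "alarp"
            else:
                zone = "unacceptable"
            zone_map[(p.name, s)] = zone
    return RiskMatrixSpec(
        probability_levels=plevels, severity_levels=slevels, zone_map=zone_map
    )


@dataclass(frozen=True)
class RiskEntry:
    """One identified risk: likelihood of harm per use plus severity level."""

    name: str
    probability: float
    severity_index: int

    def __post_init__(self) -> None:
        if not 0.0 < self.probability <= 1.0:
            raise ValueError("probability must lie in (0, 1]")
        if self.severity_index < 0:
            raise ValueError("severity_index must be non-negative")

    def combined(self, spec: RiskMatrixSpec) -> float:
        """Combined risk ``probability * severity_step ** severity_index``."""
        return combined_risk(self.probability, spec.severity_weight(self.severity_index))


def probability_level(p: float, spec: RiskMatrixSpec) -> str:
    """Name of the band whose half-open interval contains ``p``.

    Bands are ``[lower_i, lower_{i-1})`` with the top band closed at 1,
    so the ladder partitions (0, 1].
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"probability must lie in (0, 1], got {p}")
    for level in spec.probability_levels:
        if p >= level.lower and level.lower > 0:
            return level.name
    return spec.probability_levels[-1].name


def classify_risk(entry: RiskEntry, spec: RiskMatrixSpec) -> str:
    """Acceptability zone of a risk entry under the spec's zone map."""
    if entry.severity_index >= len(spec.severity_levels):
        raise ValueError(
            f"severity index {entry.severity_index} outside the "
            f"{len(spec.severity_levels)}-level grid"
        )
    p_name = probability_level(entry.probability, spec)
    s_name = spec.severity_levels[entry.severity_index]
    return spec.zone_map[(p_name, s_name)]


def combined_risk(probability: float, severity_weight: float) -> float:
    """Multiplicative combination ``probability * severity_weight``."""
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability must lie in [0, 1], got {probability}")
    if severity_weight < 0:
        raise ValueError("severity weight must be non-negative")
    return probability * severity_weight


def balanced_composition(c_fn: float, cost_ratio: float) -> float:
    """P-to-N ratio realizing risk ratio ``c_fn`` at cost ratio ``w_fn/w_fp``.

    Inverts ``c_fn = cost_ratio * (P/N)``; at ``c_fn = cost_ratio`` the
    composition is balanced (P = N), the case where prevalence and risk
    weighting cancel out.
    """
    if not (c_fn > 0 and cost_ratio > 0):
        raise ValueError("c_fn and cost_ratio must be positive")
    return c_fn / cost_ratio


def chain_hazard_to_harm(
    p_harm_given_hazard: float, base_severity_weight: float
) -> float:
    """Effective error cost after the hazard-to-harm transition.

    An FP/FN is a hazardous situation, not yet a harm; harm follows with
    conditional probability ``p2``.  Since the error rates already carry
    the hazard probability, ``p2`` is absorbed into the cost weight:
    effective weight = ``p2 * base_severity_weight``.
    """
    if not 0.0 <= p_harm_given_hazard <= 1.0:
        raise ValueError("p_harm_given_hazard must lie in [0, 1]")
    if base_severity_weight < 0:
        raise ValueError("severity weight must be non-negative")
    return p_harm_given_hazard * base_severity_weight


def read_register(path) -> list[RiskEntry]:
    """Risk register from CSV with columns ``name,probability,severity_level``.

    ``severity_level`` is a 0-based index into the spec's severity scale.
    """
    frame = pd.read_csv(path)
    required = {"name", "probability", "severity_level"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"risk register missing columns: {sorted(missing)}")
    return [
        RiskEntry(
            name=str(row["name"]),
            probability=float(row["probability"]),
            severity_index=int(row["severity_level"]),
        )
        for _, row in frame.iterrows()
    ]


def write_register(entries: Iterable[RiskEntry], path) -> None:
    pd.DataFrame(
        [
            {
                "name": e.name,
                "probability": e.probability,
                "severity_level": e.severity_index,
            }
            for e in entries
        ]
    ).to_csv(path, index=False)
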