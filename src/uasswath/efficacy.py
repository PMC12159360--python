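"""Deposition normalization and mildew-efficacy summaries for vineyard trials.

UAV and ground (backpack) sprayers apply very different volume rates (on the
order of 123 vs 378 L/ha), so raw tracer deposits (ng tracer per cm^2 of
foliage or bunch surface) are normalized by the tracer application rate
before techniques are compared.  The headline comparison is the ratio of
mean normalized ground deposit to mean normalized UAV deposit per canopy
region: near unity in the upper canopy, but severalfold less UAV deposit on
leaves near the bunches and on the bunches themselves — the likely cause of
the weaker mildew control observed for UAV-only fungicide programs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .boxstats import BoxStats, summarize_box
from .errors import ParameterError, UndefinedStatisticError

__all__ = [
    "REGIONS",
    "DepositionSample",
    "SeverityRecord",
    "normalize_deposition",
    "deposition_ratio",
    "severity_summary",
    "control_efficacy",
]

REGIONS = ("upper_canopy", "near_bunch_leaves", "bunches")
SUB_PLOTS = ("control", "UAV", "ground", "UAV+ground")


@dataclass(frozen=True)
class DepositionSample:
    technique: str  # UAV | ground
    region: str
    deposit: float  # ng tracer / cm^2
    volume_rate: float  # L/ha
    tracer_rate: float  # tracer amount applied per ha (any fixed unit)

    def __post_init__(self) -> None:
        if self.technique not in ("UAV", "ground"):
            raise ParameterError(f"unknown technique {self.technique!r}")
        if self.region not in REGIONS:
            raise ParameterError(f"unknown canopy region {self.region!r}")
        if self.deposit < 0:
            raise ParameterError("deposit must be non-negative")
        if self.volume_rate <= 0 or self.tracer_rate <= 0:
            raise ParameterError("application rates must be positive")


@dataclass(frozen=True)
class SeverityRecord:
    trial_id: str
    sub_plot: str  # control | UAV | ground | UAV+ground
    pathogen: str  # downy | powdery
    organ: str  # leaves | bunches
    severity: float  # percent of organ surface affected
    frequency: float  # percent of organs affected

    def __post_init__(self) -> None:
        if self.sub_plot not in SUB_PLOTS:
            raise ParameterError(f"unknown sub-plot {self.sub_plot!r}")
        if not (0 <= self.severity <= 100) or not (0 <= self.frequency <= 100):
            raise ParameterError("severity and frequency must lie in [0, 100]")


def normalize_deposition(sample: DepositionSample) -> float:
    """Deposit per unit tracer applied per hectare.

    Removes the volume-rate difference between techniques: doubling both the
    deposit and the tracer rate leaves the normalized value unchanged.
    """
    if sample.tracer_rate <= 0:
        raise ParameterError("tracer rate must be positive")
    return sample.deposit / sample.tracer_rate


def deposition_ratio(
    ground: Iterable[DepositionSample],
    uav: Iterable[DepositionSample],
    statistic: str = "mean",
) -> dict[str, float]:
    """Ground-to-UAV ratio of normalized deposits, per canopy region.

    A ratio of 3.6 in a region means the ground technique deposited on
    average 3.6 times more tracer per unit applied than the UAV there.
    ``statistic`` may be ``"mean"`` (default) or ``"median"``.
    """
    if statistic not in ("mean", "median"):
        raise ParameterError("statistic must be 'mean' or 'median'")
    agg = np.mean if statistic == "mean" else np.median

    def per_region(samples):
        out: dict[str, list[float]] = {}
        for s in samples:
            out.setdefault(s.region, []).append(normalize_deposition(s))
        return out

    g, u = per_region(ground), per_region(uav)
    common = [r for r in REGIONS if r in g and r in u]
    if not common:
        raise ParameterError("no canopy region present in both sample sets")
    ratios = {}
    for region in common:
        denom = float(agg(u[region]))
        if denom <= 0:
            raise UndefinedStatisticError(
                f"UAV deposit is zero in region {region!r}; ratio undefined"
            )
        ratios[region] = float(agg(g[region])) / denom
    return ratios


def severity_summary(
    records: Iterable[SeverityRecord],
    value: str = "severity",
) -> dict[tuple[str, str, str], BoxStats]:
    """Box statistics per (sub_plot, pathogen, organ) group.

    ``value`` selects ``"severity"`` or ``"frequency"``.  Empty groups are
    simply absent from the result.
    """
    if value not in ("severity", "frequency"):
        raise ParameterError("value must be 'severity' or 'frequency'")
    groups: dict[tuple[str, str, str], list[float]] = {}
    for rec in records:
        key = (rec.sub_plot, rec.pathogen, rec.organ)
        groups.setdefault(key, []).append(getattr(rec, value))
    return {key: summarize_box(vals) for key, vals in groups.items()}


def control_efficacy(treated_severity: float, control_severity: float) -> float:
    """Abbott-style control efficacy in percent: 100 x (1 - treated/control).

    Negative values (treated worse than control) are reported as-is.
    """
    if control_severity <= 0:
        raise UndefinedStatisticError(
            "control severity must be positive for efficacy to be defined"
        )
    return 100.0 * (1.0 - treated_severity / control_severity)
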