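"""Fleet-level meta-analysis across homologated UAV sprayer models.

Summarizes per-model effective swath widths as box statistics and regresses
the per-model median effective swath width against machine geometry (total
width including propellers) and maximum take-off weight (MTOW), plus the
MTOW vs total propeller working area relation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .boxstats import BoxStats, summarize_box
from .errors import DegenerateDesignError, ParameterError

__all__ = [
    "UAVModelSpec",
    "RegressionFit",
    "propeller_working_area",
    "model_summary",
    "linreg",
    "compare_correlations",
]


@dataclass
class UAVModelSpec:
    model_name: str
    total_width: float  # m, including propellers
    mtow: float  # kg, measured maximum take-off weight
    rotor_count: int
    propeller_diameter: float  # m
    nozzle_kind: str = "hydraulic"  # hydraulic | rotary
    esw_measurements: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_width <= 0 or self.mtow <= 0 or self.propeller_diameter <= 0:
            raise ParameterError("physical quantities must be positive")
        if int(self.rotor_count) != self.rotor_count or self.rotor_count < 3:
            raise ParameterError("rotor_count must be an integer >= 3")
        if self.nozzle_kind not in ("hydraulic", "rotary"):
            raise ParameterError(f"unknown nozzle kind: {self.nozzle_kind!r}")


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float
    n: int

    def predict(self, x: float) -> float:
        return self.slope * x + self.intercept


def propeller_working_area(spec: UAVModelSpec) -> float:
    """Total swept disc area of all rotors, in m^2."""
    return spec.rotor_count * math.pi * (spec.propeller_diameter / 2.0) ** 2


def model_summary(esw_measurements) -> BoxStats:
    """Box statistics of one model's measured effective swath widths."""
    return summarize_box(esw_measurements)


def linreg(x, y) -> RegressionFit:
    """Ordinary least-squares fit y = slope*x + intercept with classical SEs."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if len(x) != len(y):
        raise ParameterError("x and y must be equally long")
    if len(x) < 3:
        raise ParameterError("regression requires at least 3 points")
    if max(x) == min(x):
        raise DegenerateDesignError("x is constant: degenerate design")
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
        n=len(x),
    )


def compare_correlations(fleet: list[UAVModelSpec]) -> dict:
    """Which machine property tracks the effective swath width better?

    Fits the per-model *median* effective swath width against total UAV width
    and against MTOW, and reports both fits, their R^2, and the stronger
    predictor.
    """
    models = [m for m in fleet if m.esw_measurements]
    if len(models) < 3:
        raise ParameterError("need at least 3 models with esw measurements")
    medians = [model_summary(m.esw_measurements).median for m in models]
    widths = [m.total_width for m in models]
    mtows = [m.mtow for m in models]
    fit_width = linreg(widths, medians)
    fit_mtow = linreg(mtows, medians)
    stronger = "mtow" if fit_mtow.r_squared > fit_width.r_squared else "width"
    return {
        "n_models": len(models),
        "fit_width": fit_width,
        "fit_mtow": fit_mtow,
        "r2_width": fit_width.r_squared,
        "r2_mtow": fit_mtow.r_squared,
        "stronger_predictor": stronger,
    }
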