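"""Operational compliance rules for UAV spraying in Switzerland.

Executable encoding of three rule families:

* weather gate — gusts above 5 m/s, visibility at or below 1 km and icing
  conditions block the operation outright; mean wind above 3 m/s and shade
  temperature at or above 25 degrees C are advisory (operation discouraged
  but not prohibited);
* safety distances — a 20 m drift distance applies to treatments of field
  crops, grassland/meadows, vegetables, strawberries and lawns and to any
  herbicide treatment; a product-specific drift distance replaces the
  default when it is greater; run-off protection of surface waters requires
  3 m (6 m for farms under direct payments); UAVs above 10 kg MTOW must keep
  10 m from bystanders; the most stringent (largest) applicable distance
  governs;
* flight precision — the aircraft must hold its programmed line within
  +/- 50 cm.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ParameterError

__all__ = [
    "Verdict",
    "WeatherConditions",
    "TreatmentScenario",
    "SafetyDistances",
    "weather_gate",
    "required_safety_distance",
    "flight_precision",
    "DRIFT_DISTANCE_CROPS",
]

#: crop classes to which the 20 m default drift distance applies
DRIFT_DISTANCE_CROPS = frozenset(
    {"field_crops", "grassland", "vegetables", "strawberries", "lawns"}
)
_CROP_CLASSES = DRIFT_DISTANCE_CROPS | {"herbicide_any", "orchard", "vineyard", "other"}


class Verdict(str, Enum):
    GO = "go"
    ADVISORY = "advisory"
    NO_GO = "no_go"


@dataclass(frozen=True)
class WeatherConditions:
    temperature_shade: float  # degrees C
    gust_speed: float  # m/s
    mean_wind: float  # m/s
    visibility: float  # km
    icing: bool = False

    def __post_init__(self) -> None:
        if self.gust_speed < 0 or self.mean_wind < 0 or self.visibility < 0:
            raise ParameterError("speeds and visibility must be non-negative")


@dataclass(frozen=True)
class TreatmentScenario:
    crop_class: str
    near_surface_water: bool = False
    direct_payments: bool = False
    product_drift_distance: float | None = None
    mtow_over_10kg: bool = True

    def __post_init__(self) -> None:
        if self.crop_class not in _CROP_CLASSES:
            raise ParameterError(f"unknown crop class {self.crop_class!r}")
        if self.product_drift_distance is not None and self.product_drift_distance < 0:
            raise ParameterError("product drift distance must be non-negative")


@dataclass(frozen=True)
class SafetyDistances:
    drift_m: float
    water_m: float
    bystander_m: float
    governing_m: float


def weather_gate(cond: WeatherConditions) -> tuple[Verdict, list[str]]:
    """Evaluate weather limits; returns the verdict and all triggered reasons.

    Monotone: worsening any single condition never relaxes the verdict.
    """
    blocking: list[str] = []
    advisory: list[str] = []
    if cond.gust_speed > 5.0:
        blocking.append(
            f"wind gusts of {cond.gust_speed:g} m/s exceed the 5 m/s prohibition"
        )
    if cond.visibility <= 1.0:
        blocking.append(
            f"visibility {cond.visibility:g} km does not exceed the required 1 km"
        )
    if cond.icing:
        blocking.append("flights under icing conditions are prohibited")
    if cond.mean_wind > 3.0:
        advisory.append(
            f"mean wind {cond.mean_wind:g} m/s is above 3 m/s; spraying should be avoided"
        )
    if cond.temperature_shade >= 25.0:
        advisory.append(
            f"shade temperature {cond.temperature_shade:g} C is not below the "
            "recommended 25 C limit"
        )
    if blocking:
        return Verdict.NO_GO, blocking + advisory
    if advisory:
        return Verdict.ADVISORY, advisory
    return Verdict.GO, []


def required_safety_distance(scenario: TreatmentScenario) -> SafetyDistances:
    """Compose the applicable safety distances; the largest one governs."""
    default_drift = (
        20.0
        if scenario.crop_class in DRIFT_DISTANCE_CROPS
        or scenario.crop_class == "herbicide_any"
        else 0.0
    )
    product = scenario.product_drift_distance or 0.0
    drift = max(default_drift, product)

    water = 0.0
    if scenario.near_surface_water:
        water = 6.0 if scenario.direct_payments else 3.0

    bystander = 10.0 if scenario.mtow_over_10kg else 0.0
    return SafetyDistances(
        drift_m=drift,
        water_m=water,
        bystander_m=bystander,
        governing_m=max(drift, water, bystander),
    )


def flight_precision(track, tolerance: float = 0.5) -> tuple[float, bool]:
    """Maximum absolute lateral deviation (m) and whether it passes.

    ``track`` holds signed lateral deviations from the programmed line,
    e.g. measured over georeferenced poles; the pass tolerance defaults to
    0.5 m (+/- 50 cm).
    """
    arr = np.asarray(track, dtype=float).ravel()
    if arr.size == 0:
        raise ParameterError("empty deviation track")
    if tolerance <= 0:
        raise ParameterError("tolerance must be positive")
    max_abs = float(np.max(np.abs(arr)))
    return max_abs, max_abs <= tolerance
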