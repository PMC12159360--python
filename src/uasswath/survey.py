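"""Survey aggregation and national extrapolation of UAV-treated areas.

Authorization holders report their UAV treatments (plot, year, crop, target
pest class, canton, slope, area).  Multiple treatments of the same plot in
the same year count once toward the treated area.  Respondent totals are
extrapolated to a national estimate by the inverse response rate: with a 28%
response rate the factor is round(1/0.28, 2) = 3.57, and 471 ha of
respondent vineyard area extrapolates to floor(471 x 3.57) = 1681 ha —
11.5% of the 14 569 ha national vineyard surface.  Because non-respondents
may simply have had nothing to report, the estimate is an upper bound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "TreatmentRecord",
    "NationalEstimate",
    "TARGET_CLASSES",
    "DEFAULT_SLOPE_BANDS",
    "deduplicate",
    "aggregate",
    "extrapolation_factor",
    "national_estimate",
    "share_of_total",
    "load_survey",
    "write_survey",
]

TARGET_CLASSES = ("fungicide", "herbicide", "insecticide", "molluscicide", "biocontrol")
#: slope band cut points in percent: below the first → flat, above the last → steep
DEFAULT_SLOPE_BANDS = (18.0, 50.0)
_EXCLUDE_FLAGS = {"non_agricultural", "experimental"}


@dataclass(frozen=True)
class TreatmentRecord:
    plot_id: str
    year: int
    crop: str
    target_class: str
    canton: str
    area_ha: float
    slope_percent: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ParameterError(f"area must be positive (plot {self.plot_id})")
        if self.year < 2017:
            raise ParameterError(f"year {self.year} predates UAV spraying records")
        if self.target_class not in TARGET_CLASSES:
            raise ParameterError(f"unknown target class {self.target_class!r}")


@dataclass(frozen=True)
class NationalEstimate:
    respondent_area_ha: float
    response_rate: float
    factor: float
    estimate_ha: int
    reference_total_ha: float | None = None
    share_percent: float | None = None
    upper_bound: bool = True


def deduplicate(records: list[TreatmentRecord]) -> list[TreatmentRecord]:
    """Keep one record per (plot_id, year), first by input order.

    Warns when duplicates disagree on area; the retained (first) area counts.
    Idempotent.
    """
    seen: dict[tuple[str, int], TreatmentRecord] = {}
    for rec in records:
        key = (rec.plot_id, rec.year)
        if key in seen:
            if abs(seen[key].area_ha - rec.area_ha) > 1e-9:
                warnings.warn(
                    f"plot {rec.plot_id} year {rec.year}: conflicting areas "
                    f"({seen[key].area_ha} vs {rec.area_ha} ha); keeping first",
                    stacklevel=2,
                )
            continue
        seen[key] = rec
    return list(seen.values())


def _exclude_flagged(records):
    return [r for r in records if not (_EXCLUDE_FLAGS & set(r.flags))]


def slope_band(slope: float | None, cuts=DEFAULT_SLOPE_BANDS) -> str:
    if slope is None:
        return "unknown"
    lo, hi = cuts
    if slope < lo:
        return f"<{lo:g}%"
    if slope <= hi:
        return f"{lo:g}-{hi:g}%"
    return f">{hi:g}%"


def aggregate(
    records: list[TreatmentRecord],
    key: str,
    slope_cuts=DEFAULT_SLOPE_BANDS,
) -> dict[str, float]:
    """Sum treated area (ha) per level of ``key``.

    ``key`` is one of year, crop, target_class, canton, slope_band.  Input is
    expected deduplicated; records flagged non-agricultural or experimental
    are excluded.  Totals over all levels (including "unknown" slope) equal
    the total deduplicated area, regardless of record order.
    """
    records = _exclude_flagged(records)
    if key == "slope_band":
        keyfun = lambda r: slope_band(r.slope_percent, slope_cuts)  # noqa: E731
    elif key in ("year", "crop", "target_class", "canton"):
        keyfun = lambda r: getattr(r, key)  # noqa: E731
    else:
        raise ParameterError(f"unknown aggregation key {key!r}")
    totals: dict = {}
    for rec in records:
        level = keyfun(rec)
        totals[level] = totals.get(level, 0.0) + rec.area_ha
    return totals


def extrapolation_factor(response_rate: float) -> float:
    """Inverse response rate rounded to two decimals (0.28 → 3.57)."""
    if not (0 < response_rate <= 1):
        raise ParameterError("response rate must be in (0, 1]")
    return round(1.0 / response_rate, 2)


def national_estimate(
    respondent_area: float,
    response_rate: float,
    reference_total: float | None = None,
    nonresponse_bias: bool = True,
) -> NationalEstimate:
    """Extrapolate respondent-reported area to a national total.

    The rounded factor multiplies the respondent area, and the product is
    floored to integer hectares (471 ha at 28% → floor(1681.47) = 1681 ha).
    Flagged as an upper bound unless ``nonresponse_bias`` is disabled.
    """
    if respondent_area <= 0:
        raise ParameterError("respondent area must be positive")
    factor = extrapolation_factor(response_rate)
    estimate = int(math.floor(respondent_area * factor))
    share = (
        share_of_total(estimate, reference_total) if reference_total else None
    )
    return NationalEstimate(
        respondent_area_ha=respondent_area,
        response_rate=response_rate,
        factor=factor,
        estimate_ha=estimate,
        reference_total_ha=reference_total,
        share_percent=share,
        upper_bound=nonresponse_bias,
    )


def share_of_total(estimate: float, reference_total: float) -> float:
    """Estimated share of a reference surface, in percent to one decimal."""
    if reference_total <= 0:
        raise ParameterError("reference total must be positive")
    return round(estimate / reference_total * 100.0, 1)


_COLS = ["plot_id", "year", "crop", "target_class", "canton",
         "slope_percent", "area_ha", "flags"]


def load_survey(source) -> list[TreatmentRecord]:
    """Read treatment records from the survey CSV schema."""
    frame = pd.read_csv(source)
    missing = set(_COLS[:5] + ["area_ha"]) - set(frame.columns)
    if missing:
        raise FormatError(f"survey CSV is missing columns: {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        slope = row.get("slope_percent")
        slope = None if slope is None or pd.isna(slope) else float(slope)
        raw_flags = row.get("flags")
        flags = ()
        if raw_flags is not None and not pd.isna(raw_flags) and str(raw_flags):
            flags = tuple(f for f in str(raw_flags).split(";") if f)
        records.append(
            TreatmentRecord(
                plot_id=str(row["plot_id"]),
                year=int(row["year"]),
                crop=str(row["crop"]),
                target_class=str(row["target_class"]),
                canton=str(row["canton"]),
                area_ha=float(row["area_ha"]),
                slope_percent=slope,
                flags=flags,
            )
        )
    return records


def write_survey(records: list[TreatmentRecord], path) -> None:
    frame = pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in records],
            "year": [r.year for r in records],
            "crop": [r.crop for r in records],
            "target_class": [r.target_class for r in records],
            "canton": [r.canton for r in records],
            "slope_percent": [r.slope_percent for r in records],
            "area_ha": [r.area_ha for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )
    frame.to_csv(path, index=False)
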