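"""Lateral-wind analysis for UAV sprayer assessments.

During homologation, a UAV flies a straight line at constant speed while
three-component anemometers placed beside the flight line (10 m and 20 m
laterally, 1 m and 2 m high) record wind at 10 Hz for 50 s.  The quantity of
interest is the horizontal wind component perpendicular to the flight line:
rotor downwash and wingtip vortices can push air sideways and entrain spray
droplets off target.  Readings are deliberately not corrected for ambient
wind; trials are flown in calm conditions instead.

Sign convention: positive lateral wind blows toward the side 90 degrees
clockwise from the flight bearing (to the right of the direction of flight);
negative toward 270 degrees.  The vertical component is ignored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxstats import BoxStats, summarize_box
from .errors import FormatError, ParameterError

__all__ = ["WindSeries", "BoxStats", "lateral_component", "summarize_box",
           "pulse_stats", "load_wind"]


@dataclass(frozen=True)
class WindSeries:
    """Timestamped 3-component wind record at a fixed sensor position.

    ``u``/``v`` are the east/north horizontal components (m/s), ``w`` the
    vertical one; ``flight_bearing`` is the compass bearing (degrees) of the
    flight line; ``sensor`` is (lateral distance m, height m).
    """

    times: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    sensor: tuple[float, float] = (10.0, 1.0)
    flight_bearing: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        for name in ("u", "v", "w"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size != t.size:
                raise FormatError(f"component {name} length differs from times")
        if t.size >= 2:
            steps = np.diff(t)
            if np.any(np.abs(steps - steps[0]) > 1e-6):
                raise FormatError("wind series must be uniformly sampled")

    @property
    def rate(self) -> float:
        if self.times.size < 2:
            raise ParameterError("rate undefined for fewer than two samples")
        return 1.0 / float(self.times[1] - self.times[0])


def lateral_component(series: WindSeries) -> np.ndarray:
    """Project the horizontal wind onto the flight line's right-hand normal.

    Returns a signed speed series (m/s): positive means wind blowing toward
    the 90-degree side (right of the direction of flight).  Linear in the
    wind vector and insensitive to any along-track component.
    """
    bearing = np.deg2rad(series.flight_bearing)
    # flight direction (sin b, cos b) in (east, north); right normal is
    # (cos b, -sin b)
    return series.u * np.cos(bearing) - series.v * np.sin(bearing)


def pulse_stats(lateral, band: tuple[float, float] = (-2.0, 0.0)) -> tuple[float, float]:
    """Peak lateral wind (signed, maximum magnitude) and in-band fraction.

    ``band`` defaults to (-2, 0) m/s, the range holding the vast majority of
    lateral wind speeds observed beside homologated UAV sprayers.
    """
    arr = np.asarray(lateral, dtype=float).ravel()
    if arr.size == 0:
        raise ParameterError("empty lateral wind series")
    peak = float(arr[np.argmax(np.abs(arr))])
    lo, hi = band
    frac = float(np.mean((arr >= lo) & (arr <= hi)))
    return peak, frac


def load_wind(source) -> WindSeries:
    """Read a wind series CSV (``time_s,u_ms,v_ms,w_ms``).

    ``#``-prefixed header lines may carry ``lateral_m``, ``height_m`` and
    ``bearing_deg`` metadata.
    """
    meta: dict = {}
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, val = stripped.split(":", 1)
                meta[key.strip()] = val.strip()
            continue
        body.append(line)
    frame = pd.read_csv(io.StringIO("\n".join(body)))
    missing = {"time_s", "u_ms", "v_ms", "w_ms"} - set(frame.columns)
    if missing:
        raise FormatError(f"wind CSV is missing columns: {sorted(missing)}")
    sensor = (
        float(meta.get("lateral_m", 10.0)),
        float(meta.get("height_m", 1.0)),
    )
    return WindSeries(
        times=frame["time_s"].to_numpy(float),
        u=frame["u_ms"].to_numpy(float),
        v=frame["v_ms"].to_numpy(float),
        w=frame["w_ms"].to_numpy(float),
        sensor=sensor,
        flight_bearing=float(meta.get("bearing_deg", 0.0)),
        meta=meta,
    )
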