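"""Transversal spray-distribution analysis.

A patternator channels the liquid sprayed during a single UAV pass into a row
of collecting cylinders, giving the transversal (cross-track) liquid
distribution on a regular lateral grid.  Field treatments consist of multiple
back-and-forth passes spaced by an inter-lane distance (the swath width), so
the deposition a crop actually receives is the superposition of laterally
shifted copies of that single-pass profile.  This module simulates those
overlapped patterns, scores their uniformity with the coefficient of
variation (CV = sample standard deviation / mean x 100%), and determines the
effective swath width: the greatest inter-lane spacing whose simulated
deposition pattern has a CV below the regulatory threshold (15% by default).

Conventions
-----------
* Swath widths are restricted to integer multiples of the groove pitch; use
  :func:`resample_profile` first if a finer sweep is needed.
* Back-and-forth passes reverse the aircraft heading, so alternate passes use
  the profile mirrored about its volume-weighted center (snapped to the
  nearest half pitch so mirrored grooves stay on the grid).  Mirroring can be
  switched off for symmetric analyses.
* The CV is evaluated over a window one swath width wide centered on the
  middle pass of an odd number of passes (7 by default): the central lanes
  see the periodic steady state while the first and last lanes are
  edge-affected.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError, UndefinedStatisticError

__all__ = [
    "PatternatorProfile",
    "MultipassPattern",
    "SwathCurve",
    "load_profile",
    "trim_extent",
    "coefficient_of_variation",
    "simulate_multipass",
    "cv_curve",
    "effective_swath_width",
    "mass_balance",
    "resample_profile",
]

_GRID_ATOL = 1e-9


@dataclass(frozen=True)
class PatternatorProfile:
    """Single-pass transversal volume distribution on a regular lateral grid.

    ``positions`` are groove centers in meters (strictly increasing, regular
    pitch); ``volumes`` the collected liquid per groove (liters, or any
    proportional unit), all non-negative with at least one positive entry.
    """

    positions: np.ndarray
    volumes: np.ndarray
    pitch: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        vol = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "volumes", vol)
        if pos.ndim != 1 or pos.size != vol.size:
            raise FormatError("positions and volumes must be 1-D and equally long")
        if pos.size < 1:
            raise FormatError("profile must contain at least one groove")
        if self.pitch <= 0:
            raise ParameterError("groove pitch must be positive")
        if pos.size > 1:
            steps = np.diff(pos)
            bad = np.nonzero(np.abs(steps - self.pitch) > 1e-6)[0]
            if bad.size:
                i = int(bad[0])
                raise FormatError(
                    f"irregular groove spacing between rows {i} and {i + 1}: "
                    f"step {steps[i]:.6g} m, expected pitch {self.pitch:.6g} m"
                )
        neg = np.nonzero(vol < 0)[0]
        if neg.size:
            raise FormatError(f"negative volume at row {int(neg[0])}")
        if not np.any(vol > 0):
            raise FormatError("profile contains no positive volume")

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    @property
    def extent(self) -> float:
        """Lateral span of the grooves plus one pitch (full covered width)."""
        return float(self.positions[-1] - self.positions[0] + self.pitch)

    @property
    def center(self) -> float:
        """Volume-weighted lateral center of the distribution."""
        return float(np.average(self.positions, weights=self.volumes))


@dataclass(frozen=True)
class MultipassPattern:
    positions: np.ndarray
    deposition: np.ndarray
    swath: float
    n_passes: int
    mirrored: bool
    eval_window: tuple[float, float]
    eval_slice: tuple[int, int]

    @property
    def eval_values(self) -> np.ndarray:
        lo, hi = self.eval_slice
        return self.deposition[lo:hi]

    @property
    def cv(self) -> float:
        return coefficient_of_variation(self.eval_values)


@dataclass(frozen=True)
class SwathCurve:
    swaths: np.ndarray
    cvs: np.ndarray
    threshold: float
    compliant_band: tuple[float, ...]
    esw: float | None
    cv_min: tuple[float, float]  # (CV %, spacing m)
    contiguous: bool


def load_profile(source, pitch_tol: float = 1e-6) -> PatternatorProfile:
    """Read a single-pass profile from a CSV file.

    Expected columns ``position_m`` and ``volume``; lines starting with ``#``
    are metadata of the form ``# key: value`` and are collected into
    ``profile.meta``.
    """
    meta: dict = {}
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    lines = text.splitlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, val = stripped.split(":", 1)
                meta[key.strip()] = val.strip()
            continue
        body.append(line)
    frame = pd.read_csv(io.StringIO("\n".join(body)))
    missing = {"position_m", "volume"} - set(frame.columns)
    if missing:
        raise FormatError(f"profile CSV is missing columns: {sorted(missing)}")
    pos = frame["position_m"].to_numpy(dtype=float)
    vol = frame["volume"].to_numpy(dtype=float)
    if pos.size < 2:
        raise FormatError("profile CSV must contain at least two grooves")
    steps = np.diff(pos)
    pitch = float(steps[0])
    bad = np.nonzero(np.abs(steps - pitch) > pitch_tol)[0]
    if bad.size:
        i = int(bad[0])
        raise FormatError(
            f"irregular groove spacing at row {i + 1}: step {steps[i]:.6g} m "
            f"differs from pitch {pitch:.6g} m"
        )
    neg = np.nonzero(vol < 0)[0]
    if neg.size:
        raise FormatError(f"negative volume at row {int(neg[0])}")
    return PatternatorProfile(positions=pos, volumes=vol, pitch=pitch, meta=meta)


def trim_extent(
    profile: PatternatorProfile, rel_threshold: float = 0.01
) -> PatternatorProfile:
    """Strip leading/trailing grooves below ``rel_threshold x max(volume)``.

    Defines the profile's extent ("no overlap" means lane spacing at least as
    large as the trimmed extent); interior low grooves are kept.
    """
    if rel_threshold < 0:
        raise ParameterError("rel_threshold must be non-negative")
    cut = rel_threshold * float(profile.volumes.max())
    keep = np.nonzero(profile.volumes > cut) if rel_threshold > 0 else np.nonzero(
        profile.volumes != 0
    )
    idx = keep[0]
    if idx.size == 0:
        raise FormatError("all grooves fall below the trimming threshold")
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    return replace(
        profile,
        positions=profile.positions[lo:hi],
        volumes=profile.volumes[lo:hi],
    )


def coefficient_of_variation(values) -> float:
    """CV in percent: sample standard deviation (n-1) over the mean, x100."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 2:
        raise UndefinedStatisticError("CV requires at least two values")
    mean = arr.mean()
    if mean <= 0:
        raise UndefinedStatisticError("CV is undefined for non-positive mean")
    return float(arr.std(ddof=1) / mean * 100.0)


def _swath_steps(swath: float, pitch: float) -> int:
    k = swath / pitch
    k_int = int(round(k))
    if k_int < 1 or abs(k - k_int) > 1e-6:
        raise ParameterError(
            f"swath {swath:.6g} m is not an integer multiple of the groove "
            f"pitch {pitch:.6g} m; resample the profile to a finer grid first"
        )
    return k_int


def simulate_multipass(
    profile: PatternatorProfile,
    swath: float,
    n_passes: int = 7,
    mirrored: bool = True,
) -> MultipassPattern:
    """Superpose ``n_passes`` copies of the profile spaced ``swath`` apart.

    Pass ``k`` (k = -(n-1)/2 ... +(n-1)/2) deposits the profile shifted by
    ``k * swath``; with ``mirrored`` the profile is reversed about its
    volume-weighted center on odd passes, modelling the heading reversal of
    back-and-forth flight.  Total deposit equals ``n_passes x`` the profile
    volume exactly.
    """
    if n_passes < 3 or n_passes % 2 == 0:
        raise ParameterError("n_passes must be odd and at least 3")
    if swath <= 0:
        raise ParameterError("swath must be positive")
    k_steps = _swath_steps(swath, profile.pitch)
    half = (n_passes - 1) // 2
    p = profile.pitch
    m = profile.positions.size

    # mirror about the volume-weighted center snapped to the half-pitch grid,
    # so mirrored groove centers stay on the original grid
    center_idx = (profile.center - profile.positions[0]) / p
    snap_half = round(center_idx * 2.0) / 2.0
    forward = profile.volumes
    reverse = profile.volumes[::-1]
    # reversing the array mirrors about the array midpoint (m-1)/2; correct
    # by the offset between that midpoint and the snapped mass center
    rev_shift = int(round(2.0 * (snap_half - (m - 1) / 2.0)))

    lo_idx = -half * k_steps + min(0, rev_shift)
    hi_idx = (m - 1) + half * k_steps + max(0, rev_shift)
    n_cells = hi_idx - lo_idx + 1
    deposition = np.zeros(n_cells)
    for k in range(-half, half + 1):
        use_rev = mirrored and (k % 2 != 0)
        vols = reverse if use_rev else forward
        start = k * k_steps - lo_idx + (rev_shift if use_rev else 0)
        deposition[start : start + m] += vols

    positions = profile.positions[0] + np.arange(lo_idx, hi_idx + 1) * p
    center_pos = profile.positions[0] + snap_half * p
    # window of one swath width (at least two grooves, so the CV is defined
    # even at one-pitch spacings) centered on the middle pass
    n_win = max(k_steps, 2)
    win_lo = center_pos - n_win * p / 2.0
    i_lo = int(math.floor((win_lo - positions[0]) / p + 0.5 + 1e-6))
    i_hi = i_lo + n_win
    return MultipassPattern(
        positions=positions,
        deposition=deposition,
        swath=swath,
        n_passes=n_passes,
        mirrored=mirrored,
        eval_window=(float(positions[i_lo]) - p / 2, float(positions[i_hi - 1]) + p / 2),
        eval_slice=(i_lo, i_hi),
    )


def cv_curve(
    profile: PatternatorProfile,
    swath_min: float | None = None,
    swath_max: float | None = None,
    threshold: float = 15.0,
    n_passes: int = 7,
    mirrored: bool = True,
    trim_threshold: float = 0.01,
) -> SwathCurve:
    """CV of the simulated multi-pass pattern at every grid spacing.

    Sweeps inter-lane spacings over integer multiples of the groove pitch in
    ``[swath_min, swath_max]`` (defaulting to one pitch up to the trimmed
    profile extent), and derives the compliant band (CV strictly below
    ``threshold``) and the effective swath width (its maximum).
    """
    trimmed = trim_extent(profile, trim_threshold)
    p = trimmed.pitch
    if swath_min is None:
        swath_min = p
    if swath_max is None:
        swath_max = trimmed.extent
    if swath_min < p - 1e-9:
        raise ParameterError("swath_min must be at least one groove pitch")
    k_lo = int(math.ceil(swath_min / p - 1e-6))
    k_hi = int(math.floor(swath_max / p + 1e-6))
    if k_hi < k_lo:
        raise ParameterError("empty swath sweep range")
    swaths = np.arange(k_lo, k_hi + 1) * p
    cvs = np.array(
        [
            simulate_multipass(trimmed, float(s), n_passes=n_passes, mirrored=mirrored).cv
            for s in swaths
        ]
    )
    below = cvs < threshold
    band = tuple(float(s) for s in swaths[below])
    if band:
        esw = max(band)
        idx = np.nonzero(below)[0]
        contiguous = bool(np.all(np.diff(idx) == 1))
    else:
        esw = None
        contiguous = True
    i_min = int(np.argmin(cvs))
    return SwathCurve(
        swaths=swaths,
        cvs=cvs,
        threshold=threshold,
        compliant_band=band,
        esw=esw,
        cv_min=(float(cvs[i_min]), float(swaths[i_min])),
        contiguous=contiguous,
    )


def effective_swath_width(curve: SwathCurve) -> float | None:
    """Greatest compliant inter-lane spacing, or ``None`` if none complies.

    Warns when the compliant band is non-contiguous: the maximum still wins,
    but an interior spacing exceeded the CV threshold.
    """
    if not curve.compliant_band:
        return None
    if not curve.contiguous:
        warnings.warn(
            "compliant band is non-contiguous; reporting its maximum spacing",
            stacklevel=2,
        )
    return max(curve.compliant_band)


def mass_balance(profile: PatternatorProfile, liquid_density: float = 1.0) -> float:
    """Collected spray mass in kg (volumes in liters x density in kg/L).

    Cross-checks the patternator against the UAV weight difference between
    take-off with a full tank and landing.
    """
    if liquid_density <= 0:
        raise ParameterError("liquid density must be positive")
    return profile.total_volume * liquid_density


def resample_profile(profile: PatternatorProfile, new_pitch: float) -> PatternatorProfile:
    """Linearly interpolate groove volumes onto a finer regular grid.

    Volumes are treated as densities (volume per groove scales with pitch),
    so the total volume is conserved up to interpolation error.  Off by
    default in the analysis chain; use when a swath sweep finer than the
    measured pitch is wanted.
    """
    if new_pitch <= 0:
        raise ParameterError("new pitch must be positive")
    new_pos = np.arange(profile.positions[0], profile.positions[-1] + new_pitch / 2, new_pitch)
    density = profile.volumes / profile.pitch
    new_vol = np.interp(new_pos, profile.positions, density) * new_pitch
    return PatternatorProfile(
        positions=new_pos, volumes=new_vol, pitch=new_pitch, meta=dict(profile.meta)
    )
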