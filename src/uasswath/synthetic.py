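"""Synthetic inputs with the statistical structure the analyses assume.

No assessment dataset is publicly distributed, so every pipeline input can
be generated here: multimodal single-pass spray profiles (Gaussian plumes
under each nozzle), anemometer time series (AR(1) ambient wind plus a
UAV-induced lateral transient), fleet metadata obeying a linear
MTOW-vs-propeller-working-area relation, survey treatment records with
duplicated plot-year entries, and deposition/severity records with
region-dependent attenuation of UAV deposit.

All generators draw from a single explicitly seeded NumPy generator per
call; the same seed always reproduces the same output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .efficacy import REGIONS, DepositionSample, SeverityRecord
from .errors import ParameterError
from .fleet import UAVModelSpec
from .patternator import PatternatorProfile
from .survey import TARGET_CLASSES, TreatmentRecord
from .wind import WindSeries

__all__ = [
    "ProfileGenParams",
    "WindGenParams",
    "SurveyGenParams",
    "gen_profile",
    "gen_wind_series",
    "gen_fleet",
    "gen_survey",
    "gen_efficacy",
]


# --------------------------------------------------------------------------
# patternator profiles

@dataclass(frozen=True)
class ProfileGenParams:
    """Gaussian-mixture single-pass profile: one plume per nozzle.

    Defaults mimic a homologation run: a mid-size multirotor with nozzle
    plumes under the rotor pairs, 0.1 m groove pitch, 4.88 L collected.
    """

    nozzle_offsets: tuple[float, ...] = (-1.2, -0.4, 0.4, 1.2)
    plume_sigma: float = 0.45
    total_volume: float = 4.88
    grid_pitch: float = 0.1
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plume_sigma <= 0:
            raise ParameterError("plume sigma must be positive")
        if self.grid_pitch <= 0:
            raise ParameterError("grid pitch must be positive")
        if self.noise_cv < 0:
            raise ParameterError("noise CV must be non-negative")
        if not self.nozzle_offsets:
            raise ParameterError("at least one nozzle offset required")


def gen_profile(params: ProfileGenParams) -> PatternatorProfile:
    """Generate a single-pass transversal profile on a regular grid.

    The grid spans all plumes +/- 4 plume sigmas.  Groove volumes are exact
    Gaussian-mixture masses over each groove interval (so the total volume
    is conserved to within the <0.01% mass outside 4 sigmas) before optional
    multiplicative lognormal noise of coefficient of variation ``noise_cv``.
    """
    p = params.grid_pitch
    sig = params.plume_sigma
    lo = min(params.nozzle_offsets) - 4.0 * sig
    hi = max(params.nozzle_offsets) + 4.0 * sig
    i_lo = math.floor(lo / p)
    i_hi = math.ceil(hi / p)
    positions = np.arange(i_lo, i_hi + 1) * p
    edges_lo = positions - p / 2.0
    edges_hi = positions + p / 2.0
    volumes = np.zeros_like(positions)
    w = params.total_volume / len(params.nozzle_offsets)
    for mu in params.nozzle_offsets:
        volumes += w * (norm.cdf(edges_hi, mu, sig) - norm.cdf(edges_lo, mu, sig))
    if params.noise_cv > 0:
        rng = np.random.default_rng(params.seed)
        s = math.sqrt(math.log1p(params.noise_cv**2))
        volumes = volumes * rng.lognormal(-s * s / 2.0, s, size=volumes.size)
    return PatternatorProfile(
        positions=positions,
        volumes=volumes,
        pitch=p,
        meta={"generator": "gaussian_mixture", "seed": str(params.seed)},
    )


# --------------------------------------------------------------------------
# wind series

@dataclass(frozen=True)
class WindGenParams:
    """Ambient AR(1) wind plus a Gaussian-shaped UAV-induced lateral pulse.

    The stationary AR(1) has marginal mean ``ambient_mean`` and standard
    deviation ``ambient_sigma`` with lag-1 autocorrelation
    ``ar_coefficient``; the pulse (amplitude signed, in m/s) is centered at
    ``pulse_time`` with Gaussian width ``pulse_width``.  Defaults follow the
    assessment protocol (10 Hz for 50 s); ambient wind sampled at 10 Hz is
    strongly autocorrelated (integral timescale of seconds, hence the 0.95
    lag-1 default), and a machine passing the sensor's closest point at
    3 m/s induces a transient a couple of seconds long (sigma 1 s).
    """

    ambient_mean: float = 0.0
    ambient_sigma: float = 0.1
    ar_coefficient: float = 0.95
    pulse_amplitude: float = -1.5
    pulse_time: float = 25.0
    pulse_width: float = 1.0
    duration: float = 50.0
    rate: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.ar_coefficient) < 1:
            raise ParameterError("|ar_coefficient| must be < 1")
        n = self.duration * self.rate
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ParameterError("duration x rate must be a positive integer")
        if self.pulse_width <= 0:
            raise ParameterError("pulse width must be positive")
        if self.ambient_sigma < 0:
            raise ParameterError("ambient sigma must be non-negative")


def _ar1(rng: np.random.Generator, n: int, mean: float, sigma: float, phi: float):
    if sigma == 0:
        return np.full(n, mean)
    x = np.empty(n)
    innov_sd = sigma * math.sqrt(1.0 - phi * phi)
    x[0] = rng.normal(mean, sigma)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = mean + phi * (x[i - 1] - mean) + eps[i - 1]
    return x


def gen_wind_series(params: WindGenParams) -> WindSeries:
    """Generate a 3-component wind series beside a northbound flight line.

    The east component (lateral, positive to the right of flight) carries
    the ambient AR(1) process plus the UAV pulse; the north and vertical
    components are independent zero-mean AR(1) noise.
    """
    n = int(round(params.duration * params.rate))
    rng = np.random.default_rng(params.seed)
    times = np.arange(n) / params.rate
    lateral = _ar1(rng, n, params.ambient_mean, params.ambient_sigma,
                   params.ar_coefficient)
    pulse = params.pulse_amplitude * np.exp(
        -0.5 * ((times - params.pulse_time) / params.pulse_width) ** 2
    )
    u = lateral + pulse
    v = _ar1(rng, n, 0.0, params.ambient_sigma, params.ar_coefficient)
    w = _ar1(rng, n, 0.0, 0.5 * params.ambient_sigma, params.ar_coefficient)
    return WindSeries(
        times=times, u=u, v=v, w=w,
        sensor=(10.0, 1.0), flight_bearing=0.0,
        meta={"generator": "ar1_plus_pulse", "seed": str(params.seed)},
    )


# --------------------------------------------------------------------------
# fleet metadata

#: default MTOW per unit total propeller working area, kg/m^2, with the
#: intercept and scatter producing MTOWs in the 20-100 kg homologated range
FLEET_SLOPE_KG_PER_M2 = 14.0
FLEET_INTERCEPT_KG = 0.0
FLEET_NOISE_SD_KG = 4.0


def gen_fleet(
    n: int,
    seed: int = 0,
    slope: float = FLEET_SLOPE_KG_PER_M2,
    intercept: float = FLEET_INTERCEPT_KG,
    noise_sd: float = FLEET_NOISE_SD_KG,
    esw_noise_sd: float = 0.15,
    n_esw: int = 5,
) -> list[UAVModelSpec]:
    """Generate UAV model specs with MTOW linear in propeller working area.

    Each model draws a rotor count in {4, 6, 8} and a propeller diameter in
    [0.6, 1.4] m; MTOW = slope x area + intercept + N(0, noise_sd).  The
    median effective swath width scales with sqrt(MTOW) (heavier machines
    blow a wider downwash field), with per-assessment scatter
    ``esw_noise_sd``.
    """
    if n < 1:
        raise ParameterError("fleet size must be at least 1")
    rng = np.random.default_rng(seed)
    models = []
    for i in range(n):
        rotors = int(rng.choice([4, 6, 8]))
        diam = float(rng.uniform(0.6, 1.4))
        area = rotors * math.pi * (diam / 2.0) ** 2
        mtow = slope * area + intercept + float(rng.normal(0.0, noise_sd))
        mtow = max(mtow, 5.0)
        esw_true = 0.45 * math.sqrt(mtow) + 0.8
        esw = [
            max(0.5, esw_true + float(rng.normal(0.0, esw_noise_sd)))
            for _ in range(n_esw)
        ]
        # frame width grows with the rotor layout: roughly 2 discs across
        # plus arm clearance
        width = 2.05 * diam + float(rng.uniform(0.1, 0.5))
        models.append(
            UAVModelSpec(
                model_name=f"SYN-{i:03d}",
                total_width=width,
                mtow=mtow,
                rotor_count=rotors,
                propeller_diameter=diam,
                nozzle_kind="hydraulic" if rng.random() < 0.5 else "rotary",
                esw_measurements=esw,
            )
        )
    return models


# --------------------------------------------------------------------------
# survey records

_CANTONS = ("VS", "VD", "GE", "TI", "ZH", "BE", "AG", "GR")
_TARGET_BY_CROP = {
    "grapevine": ("fungicide", "herbicide"),
    "field_crops": ("molluscicide", "herbicide", "insecticide"),
    "meadows": ("herbicide",),
    "fruit_trees": ("fungicide",),
    "corn": ("biocontrol",),
}


@dataclass(frozen=True)
class SurveyGenParams:
    n_plots: int = 100
    years: tuple[int, ...] = (2023,)
    crop_mix: dict = field(
        default_factory=lambda: {
            "grapevine": 0.6,
            "field_crops": 0.2,
            "meadows": 0.1,
            "fruit_trees": 0.05,
            "corn": 0.05,
        }
    )
    area_range: tuple[float, float] = (0.1, 5.0)
    slope_range: tuple[float, float] = (0.0, 80.0)
    duplicate_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plots < 1:
            raise ParameterError("n_plots must be at least 1")
        if abs(sum(self.crop_mix.values()) - 1.0) > 1e-9:
            raise ParameterError("crop mix probabilities must sum to 1")
        if not (0 <= self.duplicate_rate <= 1):
            raise ParameterError("duplicate rate must be in [0, 1]")


def gen_survey(params: SurveyGenParams) -> list[TreatmentRecord]:
    """Generate treatment records, one per plot-year plus duplicates.

    With probability ``duplicate_rate`` a plot-year gains a second record of
    the same plot (a repeat treatment), which deduplication must collapse.
    """
    rng = np.random.default_rng(params.seed)
    crops = list(params.crop_mix)
    probs = np.array([params.crop_mix[c] for c in crops])
    records = []
    for i in range(params.n_plots):
        plot_id = f"P{i:04d}"
        crop = str(rng.choice(crops, p=probs))
        canton = str(rng.choice(_CANTONS))
        slope = float(rng.uniform(*params.slope_range))
        area = float(rng.uniform(*params.area_range))
        choices = _TARGET_BY_CROP.get(crop, TARGET_CLASSES)
        for year in params.years:
            target = str(rng.choice(choices))
            rec = TreatmentRecord(
                plot_id=plot_id, year=int(year), crop=crop,
                target_class=target, canton=canton,
                area_ha=area, slope_percent=slope,
            )
            records.append(rec)
            if rng.random() < params.duplicate_rate:
                records.append(rec)  # repeat treatment, same plot and year
    return records


# --------------------------------------------------------------------------
# efficacy trials

#: default region attenuation of UAV deposit relative to ground application
DEFAULT_REGION_FACTORS = {
    "upper_canopy": 1.0,
    "near_bunch_leaves": 1.0 / 3.6,
    "bunches": 1.0 / 7.1,
}
_UAV_VOLUME_RATE = 123.0  # L/ha
_GROUND_VOLUME_RATE = 378.0  # L/ha
#: mean normalized ground deposit per region (deposit per unit tracer rate);
#: deposit falls off toward the inner canopy even for ground equipment
_GROUND_NORMALIZED_MEAN = {
    "upper_canopy": 1.0,
    "near_bunch_leaves": 0.7,
    "bunches": 0.4,
}
_SEVERITY_MEANS = {  # (pathogen) -> control-plot mean severity, percent
    "downy": 35.0,
    "powdery": 55.0,
}
_SEVERITY_SCALE = {  # sub-plot severity relative to control
    "control": 1.0,
    "UAV": 0.6,
    "ground": 0.25,
    "UAV+ground": 0.2,
}


def gen_efficacy(
    seed: int = 0,
    region_factors: dict | None = None,
    n_per_region: int = 50,
    noise_cv: float = 0.3,
    n_trials: int = 6,
) -> tuple[list[DepositionSample], list[SeverityRecord]]:
    """Generate deposition samples and mildew severity records.

    UAV normalized deposit in each canopy region equals the ground mean
    times the region's attenuation factor, with multiplicative lognormal
    scatter of coefficient of variation ``noise_cv``; raw deposits are
    recovered by multiplying with each technique's tracer rate (tracer
    applied proportional to the 123 vs 378 L/ha volume rates).  Severities
    are clipped normals with control > UAV > ground on average.
    """
    factors = dict(DEFAULT_REGION_FACTORS if region_factors is None else region_factors)
    for region, fac in factors.items():
        if fac <= 0:
            raise ParameterError(f"attenuation factor for {region!r} must be positive")
    rng = np.random.default_rng(seed)
    s = math.sqrt(math.log1p(noise_cv**2))
    tracer = {"ground": _GROUND_VOLUME_RATE, "UAV": _UAV_VOLUME_RATE}
    volume = {"ground": _GROUND_VOLUME_RATE, "UAV": _UAV_VOLUME_RATE}
    deposition = []
    for region in REGIONS:
        if region not in factors:
            continue
        base = _GROUND_NORMALIZED_MEAN[region]
        for technique, mean_norm in (
            ("ground", base),
            ("UAV", base * factors[region]),
        ):
            noise = rng.lognormal(-s * s / 2.0, s, size=n_per_region)
            for z in noise:
                deposition.append(
                    DepositionSample(
                        technique=technique,
                        region=region,
                        deposit=float(mean_norm * z * tracer[technique]),
                        volume_rate=volume[technique],
                        tracer_rate=tracer[technique],
                    )
                )
    severity = []
    for t in range(n_trials):
        for pathogen, base in _SEVERITY_MEANS.items():
            for organ in ("leaves", "bunches"):
                for sub_plot, scale in _SEVERITY_SCALE.items():
                    sev = float(np.clip(rng.normal(base * scale, 8.0), 0.0, 100.0))
                    freq = float(np.clip(sev * 1.8 + rng.normal(0.0, 5.0), 0.0, 100.0))
                    severity.append(
                        SeverityRecord(
                            trial_id=f"T{t:02d}",
                            sub_plot=sub_plot,
                            pathogen=pathogen,
                            organ=organ,
                            severity=sev,
                            frequency=freq,
                        )
                    )
    return deposition, severity
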