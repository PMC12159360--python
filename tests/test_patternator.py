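"""Transversal-distribution analysis: CV, overlap simulation, esw, mass."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_profile
from overlap_oracle import brute_cv, brute_esw
from uasswath.errors import (
    FormatError,
    ParameterError,
    UndefinedStatisticError,
)
from uasswath.patternator import (
    PatternatorProfile,
    SwathCurve,
    coefficient_of_variation,
    cv_curve,
    effective_swath_width,
    load_profile,
    mass_balance,
    resample_profile,
    simulate_multipass,
    trim_extent,
)


# ----------------------------------------------------------------- loading

class TestLoadProfile:
    def test_reads_regular_profile_with_metadata(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "# model: demo\nposition_m,volume\n0.0,1\n0.1,2\n0.2,1\n"
        )
        prof = load_profile(path)
        assert prof.pitch == pytest.approx(0.1)
        assert prof.volumes.tolist() == [1.0, 2.0, 1.0]
        assert prof.meta["model"] == "demo"

    @pytest.mark.parametrize(
        "body, fragment",
        [
            ("position_m,volume\n0.0,1\n0.1,-2\n0.2,1\n", "negative volume at row 1"),
            ("position_m,volume\n0.0,1\n0.1,2\n0.25,1\n", "irregular"),
            ("position_m,vol\n0.0,1\n0.1,2\n", "missing columns"),
        ],
    )
    def test_rejects_malformed_csv(self, tmp_path, body, fragment):
        path = tmp_path / "bad.csv"
        path.write_text(body)
        with pytest.raises(FormatError, match=fragment):
            load_profile(path)


class TestProfileInvariants:
    def test_rejects_irregular_grid(self):
        with pytest.raises(FormatError):
            PatternatorProfile(
                positions=np.array([0.0, 0.1, 0.25]),
                volumes=np.ones(3),
                pitch=0.1,
            )

    def test_rejects_all_zero_volumes(self):
        with pytest.raises(FormatError):
            PatternatorProfile(
                positions=np.arange(3) * 0.1, volumes=np.zeros(3), pitch=0.1
            )


# ----------------------------------------------------------------- trimming

class TestTrimExtent:
    def test_strips_outer_low_grooves(self):
        prof = PatternatorProfile(
            positions=np.arange(5) * 0.1,
            volumes=np.array([0.0, 0.0, 5.0, 3.0, 0.0]),
            pitch=0.1,
        )
        trimmed = trim_extent(prof)
        assert trimmed.volumes.tolist() == [5.0, 3.0]
        assert trimmed.extent == pytest.approx(0.2)  # groove span + one pitch

    def test_zero_threshold_trims_only_exact_zeros(self):
        prof = PatternatorProfile(
            positions=np.arange(4) * 0.1,
            volumes=np.array([0.0, 0.001, 5.0, 0.0]),
            pitch=0.1,
        )
        assert trim_extent(prof, 0.0).volumes.tolist() == [0.001, 5.0]

    def test_identity_when_no_tails(self, box_profile):
        trimmed = trim_extent(box_profile)
        assert np.array_equal(trimmed.volumes, box_profile.volumes)

    def test_all_below_threshold_errors(self, box_profile):
        with pytest.raises(FormatError):
            trim_extent(box_profile, rel_threshold=2.0)


# ----------------------------------------------------------------- CV

class TestCoefficientOfVariation:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5, 5, 5, 5], 0.0),
            ([1, 2, 3, 4], 51.64),  # sample sd 1.2910 / mean 2.5 x 100
        ],
    )
    def test_known_values(self, values, expected):
        assert coefficient_of_variation(values) == pytest.approx(expected, abs=0.005)

    def test_scale_invariance(self):
        assert coefficient_of_variation([1, 2, 3]) == pytest.approx(
            coefficient_of_variation([10, 20, 30])
        )

    def test_undefined_cases(self):
        with pytest.raises(UndefinedStatisticError):
            coefficient_of_variation([0.0, 0.0])
        with pytest.raises(UndefinedStatisticError):
            coefficient_of_variation([1.0])


# ----------------------------------------------------------------- overlap

class TestSimulateMultipass:
    @pytest.mark.parametrize("mirrored", [True, False])
    def test_uniform_profile_tiles_perfectly_at_extent(self, box_profile, mirrored):
        pat = simulate_multipass(box_profile, swath=1.0, mirrored=mirrored)
        assert pat.cv == pytest.approx(0.0, abs=1e-9)

    def test_triangle_base2_constant_at_half_base(self, triangle_profile):
        pat = simulate_multipass(triangle_profile, swath=1.0)
        assert pat.cv == pytest.approx(0.0, abs=1e-9)

    def test_box_at_double_extent_half_covered(self, box_profile):
        # window of 20 grooves, 10 at deposit 1 and 10 at 0:
        # CV = 100 * sqrt(20/19) under the sample-sd convention
        pat = simulate_multipass(box_profile, swath=2.0)
        assert pat.cv == pytest.approx(100.0 * math.sqrt(20.0 / 19.0), rel=1e-9)

    @pytest.mark.parametrize("mirrored", [True, False])
    @pytest.mark.parametrize("k", [1, 3, 7, 12])
    def test_conservation(self, triangle_profile, mirrored, k):
        pat = simulate_multipass(triangle_profile, swath=k * 0.1, mirrored=mirrored)
        assert pat.deposition.sum() == pytest.approx(
            pat.n_passes * triangle_profile.total_volume, rel=1e-12
        )

    def test_off_grid_swath_rejected(self, box_profile):
        with pytest.raises(ParameterError, match="resample"):
            simulate_multipass(box_profile, swath=0.25)

    @pytest.mark.parametrize("n_passes", [2, 4, 1])
    def test_even_or_too_few_passes_rejected(self, box_profile, n_passes):
        with pytest.raises(ParameterError):
            simulate_multipass(box_profile, swath=0.5, n_passes=n_passes)

    def test_asymmetric_profile_mirroring_conserves_mass(self):
        prof = PatternatorProfile(
            positions=np.arange(8) * 0.1,
            volumes=np.array([0.2, 1.0, 3.0, 2.0, 1.0, 0.5, 0.3, 0.1]),
            pitch=0.1,
        )
        pat = simulate_multipass(prof, swath=0.4, mirrored=True)
        assert pat.deposition.sum() == pytest.approx(7 * prof.total_volume)


# ----------------------------------------------------------------- cv curve

class TestCvCurve:
    def test_triangle_sweep_has_esw_at_least_half_base(self, triangle_profile):
        curve = cv_curve(triangle_profile, swath_min=0.5, swath_max=2.0)
        esw = effective_swath_width(curve)
        assert esw is not None and esw >= 1.0

    def test_matches_brute_force_oracle_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            prof = random_profile(rng)
            curve = cv_curve(prof, trim_threshold=0.0)
            trimmed = trim_extent(prof, 0.0)
            cvs, esw = brute_esw(
                trimmed.positions, trimmed.volumes, trimmed.pitch, curve.swaths
            )
            np.testing.assert_allclose(curve.cvs, cvs, rtol=1e-9, atol=1e-9)
            assert effective_swath_width(curve) == (
                pytest.approx(esw) if esw is not None else None
            )

    def test_single_swath_matches_brute_cv(self, triangle_profile):
        pat = simulate_multipass(triangle_profile, swath=0.7)
        expected = brute_cv(
            triangle_profile.positions,
            triangle_profile.volumes,
            triangle_profile.pitch,
            0.7,
        )
        assert pat.cv == pytest.approx(expected, rel=1e-12)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            prof = random_profile(rng)
            lo = cv_curve(prof, threshold=10.0)
            hi = cv_curve(prof, threshold=25.0)
            esw_lo = effective_swath_width(lo)
            esw_hi = effective_swath_width(hi)
            if esw_lo is not None:
                assert esw_hi is not None and esw_hi >= esw_lo

    def test_empty_sweep_rejected(self, box_profile):
        with pytest.raises(ParameterError):
            cv_curve(box_profile, swath_min=0.9, swath_max=0.85)


class TestEffectiveSwathWidth:
    def _curve(self, swaths, cvs, threshold=15.0):
        swaths = np.asarray(swaths, float)
        cvs = np.asarray(cvs, float)
        below = cvs < threshold
        idx = np.nonzero(below)[0]
        band = tuple(float(s) for s in swaths[below])
        return SwathCurve(
            swaths=swaths,
            cvs=cvs,
            threshold=threshold,
            compliant_band=band,
            esw=max(band) if band else None,
            cv_min=(float(cvs.min()), float(swaths[int(np.argmin(cvs))])),
            contiguous=bool(idx.size == 0 or np.all(np.diff(idx) == 1)),
        )

    def test_greatest_compliant_spacing_wins(self):
        curve = self._curve([2.4, 2.6, 2.8, 3.0, 3.2], [10, 8, 9, 14, 20])
        assert effective_swath_width(curve) == pytest.approx(3.0)

    def test_none_when_nothing_complies(self):
        curve = self._curve([1.0, 2.0], [30, 40])
        assert effective_swath_width(curve) is None

    def test_non_contiguous_band_warns_but_takes_maximum(self):
        curve = self._curve([1.0, 1.6, 2.2], [10, 20, 12])
        with pytest.warns(UserWarning, match="non-contiguous"):
            assert effective_swath_width(curve) == pytest.approx(2.2)


# ----------------------------------------------------------------- mass

class TestMassBalance:
    def test_collected_volume_to_weight_difference(self):
        # full-tank homologation run: 4.88 L of water collected means the
        # aircraft landed about 5 kg lighter than it took off
        vols = np.full(61, 4.88 / 61)
        prof = PatternatorProfile(np.arange(61) * 0.1, vols, 0.1)
        mass = mass_balance(prof)
        assert mass == pytest.approx(4.88)
        assert round(mass) == 5

    def test_density_scales_mass(self, box_profile):
        assert mass_balance(box_profile, liquid_density=1.0) == pytest.approx(10.0)

    def test_invalid_density(self, box_profile):
        with pytest.raises(ParameterError):
            mass_balance(box_profile, liquid_density=0.0)


# ----------------------------------------------------------------- property

@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    volumes=st.lists(
        st.floats(min_value=0.0, max_value=10.0), min_size=4, max_size=40
    ).filter(lambda v: max(v) > 0.1),
    k=st.integers(min_value=1, max_value=10),
    mirrored=st.booleans(),
)
def test_conservation_property(volumes, k, mirrored):
    """Total deposit is n_passes x profile volume for any swath/mirroring."""
    prof = PatternatorProfile(
        positions=np.arange(len(volumes)) * 0.1,
        volumes=np.asarray(volumes),
        pitch=0.1,
    )
    pat = simulate_multipass(prof, swath=k * 0.1, mirrored=mirrored)
    assert pat.deposition.sum() == pytest.approx(7 * prof.total_volume, rel=1e-9)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    volumes=st.lists(
        st.floats(min_value=0.01, max_value=10.0), min_size=4, max_size=25
    ),
    scale=st.floats(min_value=0.01, max_value=100.0),
)
def test_cv_scale_invariance_property(volumes, scale):
    arr = np.asarray(volumes)
    assert coefficient_of_variation(arr * scale) == pytest.approx(
        coefficient_of_variation(arr), rel=1e-9
    )


def test_resample_conserves_volume(triangle_profile):
    fine = resample_profile(triangle_profile, 0.05)
    assert fine.pitch == pytest.approx(0.05)
    assert fine.total_volume == pytest.approx(triangle_profile.total_volume, rel=0.01)
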