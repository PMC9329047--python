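import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from benthicflux.errors import (
    AlignmentError,
    DataError,
    InsufficientDataError,
    NoInteriorPeakError,
)
from benthicflux.physchem import (
    CM2_PER_S_TO_M2_PER_D,
    DiffusivityEntry,
    DiffusivityRegistry,
    SedimentProperties,
)
from benthicflux.profile_flux import (
    DepthProfile,
    diffusive_flux,
    extract_features,
    fit_gradient,
    peak_partition,
)
from benthicflux.synthetic import make_steady_profile


def linear_profile(slope, intercept=0.0, n=10, spacing=1e-3, species="Fe2+"):
    depths = np.arange(n) * spacing
    return DepthProfile(species=species, depths=depths,
                        concentrations=intercept + slope * depths)


class TestDepthProfile:
    def test_requires_increasing_depths(self):
        with pytest.raises(DataError):
            DepthProfile("Fe2+", [0.0, 0.0, 0.01], [1, 2, 3])

    def test_requires_two_points(self):
        with pytest.raises(DataError):
            DepthProfile("Fe2+", [0.0], [1.0])

    def test_negative_concentrations_floored(self):
        p = DepthProfile("Fe2+", [0.0, 0.01], [-0.5, 2.0])
        assert p.concentrations[0] == 0.0


class TestFitGradient:
    def test_two_point_line(self):
        p = DepthProfile("Fe2+", [0.0, 0.01], [10.0, 20.0])
        fit = fit_gradient(p, (0.0, 0.02))
        assert fit.slope == pytest.approx(1000.0)
        assert fit.stderr is None  # undefined for exactly 2 points
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_profile(self):
        p = linear_profile(0.0, intercept=7.0)
        fit = fit_gradient(p, (0.0, 1.0))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0  # undefined-by-convention

    def test_noisy_line_within_3_se(self, rng):
        depths = np.arange(10) * 1e-3
        conc = 5.0 + 300.0 * depths + 0.05 * rng.standard_normal(10)
        p = DepthProfile("Fe2+", depths, conc)
        fit = fit_gradient(p, (0.0, 1.0))
        # independent oracle: closed-form OLS via numpy least squares
        a = np.vstack([depths, np.ones_like(depths)]).T
        slope_ref = np.linalg.lstsq(a, conc, rcond=None)[0][0]
        assert fit.slope == pytest.approx(slope_ref, rel=1e-10)
        assert abs(fit.slope - 300.0) <= 3 * fit.stderr

    def test_half_open_window(self):
        p = linear_profile(100.0, n=5, spacing=1e-3)
        fit = fit_gradient(p, (0.0, 2e-3))  # [0, 2) mm -> exactly 2 points
        assert fit.n_points == 2

    def test_insufficient_points(self):
        p = linear_profile(100.0)
        with pytest.raises(InsufficientDataError):
            fit_gradient(p, (0.05, 0.06))


class TestDiffusiveFlux:
    def test_zero_slope_zero_flux(self, props):
        p = linear_profile(0.0, intercept=3.0, species="dFe")
        assert diffusive_flux(p, props, (0.0, 1.0)).flux == 0.0

    def test_hand_value(self):
        # D0 fixed at 1e-5 cm2 s-1 = 8.64e-5 m2 d-1 via a custom registry
        reg = DiffusivityRegistry([DiffusivityEntry("X", 10.0, 0.0)])
        props = SedimentProperties(porosity=0.85, salinity=0.0, temperature=4.0)
        p = linear_profile(100.0, species="X")
        res = diffusive_flux(p, props, (0.0, 1.0), registry=reg)
        theta2 = props.tortuosity_squared
        assert res.flux == pytest.approx(-0.85 * (8.64e-5 / theta2) * 100.0)
        assert res.flux == pytest.approx(-5.543e-3, abs=1e-6)

    def test_sign_convention(self, props):
        # concentration increasing with depth -> upward (negative) flux
        p = linear_profile(100.0, species="dFe")
        assert diffusive_flux(p, props, (0.0, 1.0)).flux < 0

    def test_flux_slope_invariant(self, props):
        p = linear_profile(250.0, intercept=1.0, species="dFe")
        res = diffusive_flux(p, props, (0.0, 1.0))
        expected = res.porosity * (res.d0 / res.tortuosity_squared) * abs(res.slope)
        assert abs(res.flux) == pytest.approx(expected, rel=1e-14)

    def test_two_layer_recovery_within_1pct(self, props):
        # generator truth: upward flux 1.4 mmol m-2 d-1 on a 0.5 mm grid
        profile, truth = make_steady_profile(
            "dFe", 1.4 / 0.78, 0.78, production_depth=5e-3,
            props=props, grid_spacing=0.5e-3,
        )
        res = diffusive_flux(profile, props, (0.0, 2.1e-3))
        assert res.flux == pytest.approx(-1.4, rel=0.01)

    def test_provenance_fields(self, props):
        p = linear_profile(10.0, species="dAs")
        res = diffusive_flux(p, props, (0.0, 1.0))
        assert res.species == "dAs"
        assert res.registry_species == "HAsO4--"
        assert res.porosity == props.porosity


def tent_profile(peak_idx=10, n=21, spacing=1e-3, peak=100.0, species="dFe"):
    depths = np.arange(n) * spacing
    conc = peak - np.abs(depths - depths[peak_idx]) * (peak / (peak_idx * spacing))
    return DepthProfile(species=species, depths=depths, concentrations=conc)


class TestPeakPartition:
    def test_symmetric_tent_splits_evenly(self, props):
        part = peak_partition(tent_profile(), props)
        assert part.upward_fraction == pytest.approx(0.5)
        assert part.downward_fraction == pytest.approx(0.5)

    def test_fractions_sum_to_one(self, props):
        profile, _ = make_steady_profile(
            "dFe", 2.3, 0.6, production_depth=15e-3, props=props
        )
        part = peak_partition(profile, props)
        assert 0.0 <= part.upward_fraction <= 1.0
        assert part.upward_fraction + part.downward_fraction == pytest.approx(1.0)

    def test_generator_truth_recovery(self, props):
        profile, truth = make_steady_profile(
            "dFe", 2.3, 0.6, production_depth=15e-3, props=props, grid_spacing=0.5e-3
        )
        part = peak_partition(profile, props)
        assert part.production == pytest.approx(2.3, rel=0.02)
        assert part.upward_fraction == pytest.approx(0.6, rel=0.02)

    def test_monotone_profile_raises(self, props):
        with pytest.raises(NoInteriorPeakError):
            peak_partition(linear_profile(100.0, species="dFe"), props)

    def test_tie_broken_toward_depth(self, props):
        depths = np.arange(7) * 1e-3
        conc = np.array([0.0, 5.0, 9.0, 9.0, 9.0, 4.0, 0.0])
        part = peak_partition(DepthProfile("dFe", depths, conc), props, 2)
        assert part.peak_depth == pytest.approx(4e-3)

    def test_constant_offset_invariance(self, props):
        base = tent_profile(peak_idx=8, n=20)
        shifted = DepthProfile(
            base.species, base.depths, base.concentrations + 50.0
        )
        p1 = peak_partition(base, props)
        p2 = peak_partition(shifted, props)
        assert p2.production == pytest.approx(p1.production, rel=1e-12)


def o2_profile(opd_m=1.4e-3, bw=329.0, limit=1.0):
    # linear from bottom water at SWI to the limit exactly at opd, then to zero
    depths = np.array([-1e-3, 0.0, opd_m, opd_m + 1e-3, 5e-3])
    conc = np.array([bw, bw, limit, 0.0, 0.0])
    return DepthProfile("O2", depths, conc)


def h2s_profile(sad_m=41e-3, limit=1.0, slope=1000.0):
    x0 = sad_m - limit / slope
    depths = np.array([-1e-3, 0.0, x0, 60e-3])
    conc = np.array([0.0, 0.0, 0.0, (60e-3 - x0) * slope])
    return DepthProfile("H2S", depths, conc)


def ph_profile():
    depths = np.array([-1e-3, 1.4e-3, 20e-3, 41e-3, 60e-3])
    conc = np.array([8.1, 8.82, 7.2, 6.4, 6.6])
    return DepthProfile("pH", depths, conc)


class TestExtractFeatures:
    def test_constructed_crossings(self):
        f = extract_features(o2_profile(), h2s_profile(), ph_profile())
        assert f.opd == pytest.approx(1.4e-3, rel=1e-9)
        assert f.sad == pytest.approx(41e-3, rel=1e-9)
        assert f.suboxic_thickness == pytest.approx(39.6e-3, rel=1e-9)
        assert f.sad >= f.opd

    def test_ph_extrema(self):
        f = extract_features(o2_profile(), h2s_profile(), ph_profile())
        assert f.ph_max_value == pytest.approx(8.82)
        assert f.ph_max_depth == pytest.approx(1.4e-3)
        assert f.ph_min_value == pytest.approx(6.4)
        assert f.ph_min_depth == pytest.approx(41e-3)

    def test_all_zero_sulfide_undefined(self):
        flat = DepthProfile("H2S", [-1e-3, 0.0, 60e-3], [0.0, 0.0, 0.0])
        f = extract_features(o2_profile(), flat, ph_profile())
        assert f.sad is None
        assert f.suboxic_thickness is None

    def test_oxygen_never_depleted_undefined(self):
        rich = DepthProfile("O2", [-1e-3, 0.0, 5e-3], [300.0, 300.0, 250.0])
        f = extract_features(rich, h2s_profile(), ph_profile())
        assert f.opd is None

    def test_alignment_error(self):
        deep_ph = DepthProfile("pH", [0.2, 0.3], [7.0, 7.1])
        with pytest.raises(AlignmentError):
            extract_features(o2_profile(), h2s_profile(), deep_ph)

    @given(limit2=st.floats(1.5, 50.0))
    def test_opd_non_increasing_in_detection_limit(self, limit2):
        # monotone-decreasing O2: a higher limit is crossed shallower
        o2 = o2_profile(bw=329.0)
        f1 = extract_features(o2, h2s_profile(), ph_profile(), detection_limit=1.0)
        f2 = extract_features(o2, h2s_profile(), ph_profile(), detection_limit=limit2)
        assert f2.opd <= f1.opd

    def test_bad_detection_limit(self):
        with pytest.raises(DataError):
            extract_features(o2_profile(), h2s_profile(), ph_profile(), 0.0)
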