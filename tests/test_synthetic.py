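import numpy as np
import pytest

from benthicflux.errors import DataError, RangeError
from benthicflux.incubation import detect_onset, interval_fluxes
from benthicflux.profile_flux import diffusive_flux, extract_features, peak_partition
from benthicflux.synthetic import (
    ConstantFlux,
    DelayedPulse,
    ExponentialPulse,
    LogisticOnset,
    SaturatingFlux,
    make_attenuation_profile,
    make_scenario,
    make_steady_profile,
    preset_names,
    simulate_incubation,
)


class TestFluxHistories:
    @pytest.mark.parametrize(
        "fh",
        [
            ConstantFlux(1.3),
            ExponentialPulse(4.0, 30.0),
            LogisticOnset(6.0, 75.0, 4.0),
            DelayedPulse(3e-3, 50.0),
            SaturatingFlux(7.0, 10.0),
        ],
    )
    def test_analytic_integral_matches_quadrature(self, fh):
        from scipy.integrate import quad

        for t0, t1 in [(0.0, 7.0), (40.0, 60.0), (0.0, 161.0)]:
            num, _ = quad(lambda t: float(fh(t)), t0, t1, limit=200)
            assert fh.integral(t0, t1) == pytest.approx(num, rel=1e-8)

    def test_delayed_pulse_peaks_at_peak_time(self):
        fh = DelayedPulse(3.0, 50.0)
        t = np.linspace(0, 200, 2001)
        assert t[np.argmax(fh(t))] == pytest.approx(50.0, abs=0.1)
        assert float(fh(50.0)) == pytest.approx(3.0)


class TestMakeSteadyProfile:
    def test_zero_rate_flat_profile(self, props):
        profile, truth = make_steady_profile("dFe", 0.0, 0.5, 15e-3, props)
        assert np.all(profile.concentrations == 0.0)
        assert truth.production_rate == 0.0

    def test_seeding_contract(self, props):
        a, _ = make_steady_profile("dFe", 2.3, 0.6, 15e-3, props, noise_cv=0.05, seed=4)
        b, _ = make_steady_profile("dFe", 2.3, 0.6, 15e-3, props, noise_cv=0.05, seed=4)
        c, _ = make_steady_profile("dFe", 2.3, 0.6, 15e-3, props, noise_cv=0.05, seed=5)
        assert np.array_equal(a.concentrations, b.concentrations)
        assert not np.array_equal(a.concentrations, c.concentrations)

    def test_partition_recovers_truth(self, props):
        profile, _ = make_steady_profile(
            "dFe", 2.3, 0.6, 15e-3, props, grid_spacing=0.5e-3
        )
        part = peak_partition(profile, props)
        assert part.production == pytest.approx(2.3, rel=0.02)
        assert part.upward_fraction == pytest.approx(0.6, rel=0.02)

    def test_infeasible_geometry(self, props):
        with pytest.raises(DataError):
            make_steady_profile(
                "dFe", 2.3, 0.6, 15e-3, props, consumption_depth=20e-3
            )

    def test_invalid_inputs(self, props):
        with pytest.raises(RangeError):
            make_steady_profile("dFe", -1.0, 0.6, 15e-3, props)
        with pytest.raises(DataError):
            make_steady_profile("dFe", 2.3, 0.6, 80e-3, props, extent=60e-3)


class TestGridRefinement:
    def test_flux_error_shrinks_monotonically(self, props):
        # smooth generator profile: finite window sees curvature, so the
        # estimate converges as the grid is refined (4 halving levels)
        errors = []
        for h in (4e-3, 2e-3, 1e-3, 0.5e-3):
            profile, true_flux = make_attenuation_profile(
                "dFe", 100.0, 10e-3, props, grid_spacing=h
            )
            est = diffusive_flux(profile, props, (0.0, 3.5 * h))
            errors.append(abs(est.flux - true_flux))
        assert all(b < a for a, b in zip(errors, errors[1:]))
        assert errors[-1] < 0.2 * errors[0]


class TestSimulateIncubation:
    def test_constant_flux_exact(self):
        series, ledger = simulate_incubation(
            {"dFe": ConstantFlux(1.0)}, np.arange(0.0, 71.0, 7.0)
        )
        for iv in interval_fluxes(series["dFe"]).intervals:
            assert iv.flux == pytest.approx(1.0, rel=1e-12)

    def test_zero_flux_tracks_replacement_water(self):
        series, _ = simulate_incubation(
            {"dFe": ConstantFlux(0.0)},
            np.arange(0.0, 29.0, 7.0),
            replacement_fraction=1.0,
            conc_repl=2.5,
            initial_conc=9.0,
        )
        events = series["dFe"].events
        assert events[0].conc_end == 9.0
        for e in events[1:]:
            assert e.conc_end == pytest.approx(2.5)

    def test_determinism(self):
        kwargs = dict(noise_cv=0.05, seed=11)
        a, _ = simulate_incubation(
            {"dFe": ConstantFlux(1.0)}, np.arange(0.0, 71.0, 7.0), **kwargs
        )
        b, _ = simulate_incubation(
            {"dFe": ConstantFlux(1.0)}, np.arange(0.0, 71.0, 7.0), **kwargs
        )
        assert [e.conc_end for e in a["dFe"].events] == [
            e.conc_end for e in b["dFe"].events
        ]

    def test_bad_schedule(self):
        with pytest.raises(DataError):
            simulate_incubation({"x": ConstantFlux(1.0)}, [0.0])


class TestScenarios:
    def test_preset_names(self):
        assert preset_names() == ["august", "march", "may"]

    def test_unknown_preset_lists_available(self):
        with pytest.raises(DataError, match="march"):
            make_scenario("winter")

    def test_bit_identical_with_same_seed(self):
        a = make_scenario("march", seed=2, noise_cv=0.05)
        b = make_scenario("march", seed=2, noise_cv=0.05)
        for key in a.profiles:
            assert np.array_equal(
                a.profiles[key].concentrations, b.profiles[key].concentrations
            )
        for sp in a.incubations:
            assert [e.conc_end for e in a.incubations[sp].events] == [
                e.conc_end for e in b.incubations[sp].events
            ]

    def test_march_features(self):
        sc = make_scenario("march", seed=1)
        f = extract_features(sc.profiles["O2"], sc.profiles["H2S"], sc.profiles["pH"])
        assert f.opd == pytest.approx(1.4e-3, rel=1e-6)
        assert f.sad == pytest.approx(41e-3, rel=1e-6)
        assert f.suboxic_thickness == pytest.approx(39.6e-3, rel=1e-6)
        assert f.ph_max_value == pytest.approx(8.82)
        assert f.ph_min_value == pytest.approx(6.4)

    def test_may_dfe_partition(self):
        sc = make_scenario("may", seed=1)
        part = peak_partition(sc.profiles["dFe"], sc.props)
        assert part.production == pytest.approx(1.4, rel=0.02)
        assert part.upward_fraction == pytest.approx(0.78, rel=0.02)

    def test_august_sulfide_from_interface(self):
        sc = make_scenario("august", seed=1)
        f = extract_features(sc.profiles["O2"], sc.profiles["H2S"], sc.profiles["pH"])
        assert f.sad == pytest.approx(0.0, abs=1e-6)
        assert f.opd == pytest.approx(0.0, abs=1e-6)
        assert detect_onset(sc.incubations["H2S"]) == 7.0

    def test_march_sulfide_onset_delayed(self):
        sc = make_scenario("march", seed=1)
        onset = detect_onset(sc.incubations["H2S"])
        assert 50.0 <= onset <= 100.0

    def test_may_sulfide_onset_window(self):
        sc = make_scenario("may", seed=1)
        onset = detect_onset(sc.incubations["H2S"])
        assert 30.0 <= onset <= 50.0

    def test_march_as_flux_peaks_near_day_50(self):
        sc = make_scenario("march", seed=1)
        fs = interval_fluxes(sc.incubations["dAs"])
        peak_iv = max(fs.intervals, key=lambda iv: iv.flux)
        assert peak_iv.t_start <= 50.0 <= peak_iv.t_end + 7.0

    def test_ledger_consistency(self):
        # ledger totals equal the analytic time-integrals of the flux functions
        sc = make_scenario("may", seed=1)
        area = sc.incubations["dFe"].core_area
        t0, t1 = sc.truth.schedule[0], sc.truth.schedule[-1]
        for sp, fh in sc.truth.incubation_flux.items():
            expected = fh.integral(float(t0), float(t1)) * area * 1000.0
            assert sc.truth.released_umol[sp] == pytest.approx(expected, rel=1e-9)

    def test_august_no_metal_efflux(self):
        sc = make_scenario("august", seed=1)
        assert sc.truth.cumulative_mmol_m2["dFe"] == 0.0
        assert sc.truth.cumulative_mmol_m2["dAs"] == 0.0


class TestNoiseRecovery:
    def test_median_relative_error_under_5pct(self, props):
        # 5 % multiplicative noise, 100 seeds, wide fit windows
        errors_rate = []
        errors_frac = []
        for seed in range(100):
            profile, _ = make_steady_profile(
                "dFe", 2.3, 0.6, 15e-3, props,
                grid_spacing=0.5e-3, noise_cv=0.05, seed=seed,
            )
            part = peak_partition(profile, props, peak_window_size=24)
            errors_rate.append(abs(part.production - 2.3) / 2.3)
            errors_frac.append(abs(part.upward_fraction - 0.6) / 0.6)
        assert float(np.median(errors_rate)) <= 0.05
        assert float(np.median(errors_frac)) <= 0.05
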