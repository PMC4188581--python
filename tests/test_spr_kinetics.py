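"""Two-state SPR kinetics: derivations, simulation, global fitting."""

import numpy as np
import pytest

from allopep.pipeline import DEFAULT_SINGLE_CYCLE_SCHEDULE
from allopep.reference import TWO_STATE_RATE_SETS
from allopep.spr_kinetics import (
    NOT_SIGNIFICANT,
    POSSIBLE_COMPETITION,
    InjectionSeries,
    InvalidScheduleError,
    Sensorgram,
    TwoStateRates,
    atp_competition_call,
    derive_equilibrium,
    fit_two_state,
    simulate_sensorgram,
)

DAALT_RATES = TwoStateRates(434.1, 23.2e-3, 14.1e-4, 1.3e-5)


class TestDeriveEquilibrium:
    @pytest.mark.parametrize(
        "rate_set", TWO_STATE_RATE_SETS, ids=lambda rs: f"{rs.printed_label}_{'atp' if rs.with_atp else 'apo'}"
    )
    def test_published_rates_reproduce_published_kd(self, rate_set):
        """Each published rate set reproduces its printed K_D within the
        printed uncertainty or 10% relative (printed rates are rounded)."""
        derived = derive_equilibrium(rate_set.rates)
        err = abs(derived.K_D - rate_set.printed_kd_m)
        assert (
            err <= rate_set.printed_kd_uncertainty_m
            or err / rate_set.printed_kd_m <= 0.10
        )

    def test_langmuir_limit(self):
        rates = TwoStateRates(100.0, 1e-2, 0.0, 0.0)
        d = derive_equilibrium(rates)
        assert d.K_2 == 0.0
        assert d.K_D == pytest.approx(1e-2 / 100.0)

    def test_zero_kd1_rejected(self):
        with pytest.raises(ZeroDivisionError):
            derive_equilibrium(TwoStateRates(1.0, 0.0, 1.0, 1.0))

    def test_internal_consistency(self):
        d = derive_equilibrium(DAALT_RATES)
        assert d.K_A == pytest.approx(d.K_1 * (1 + d.K_2))
        assert d.K_D == pytest.approx(1.0 / d.K_A)


class TestSchedule:
    def test_overlapping_injections_rejected(self):
        with pytest.raises(InvalidScheduleError):
            InjectionSeries(((1e-6, 0, 100), (2e-6, 50, 150)), 500)

    def test_decreasing_concentrations_rejected(self):
        with pytest.raises(InvalidScheduleError):
            InjectionSeries(((2e-6, 0, 100), (1e-6, 200, 300)), 500)

    def test_concentration_lookup(self):
        s = InjectionSeries(((1e-6, 10, 20),), 100)
        assert s.concentration_at(15) == 1e-6
        assert s.concentration_at(5) == 0.0
        assert s.concentration_at(20) == 0.0  # stop is exclusive


class TestSimulate:
    def test_zero_concentration_gives_zero_response(self):
        s = InjectionSeries(((0.0, 0, 100),), 300)
        gram = simulate_sensorgram(DAALT_RATES, 100.0, s)
        np.testing.assert_allclose(gram.response_ru, 0.0, atol=1e-12)

    def test_zero_on_rate_gives_flat_response(self):
        s = InjectionSeries(((1e-5, 0, 100),), 300)
        rates = TwoStateRates(0.0, 1e-2, 1e-3, 1e-4)
        gram = simulate_sensorgram(rates, 100.0, s)
        np.testing.assert_allclose(gram.response_ru, 0.0, atol=1e-12)

    def test_rise_during_injection_decay_after(self):
        """Published TAALS rates: response rises while analyte flows, decays after."""
        taals = TWO_STATE_RATE_SETS[0].rates
        s = InjectionSeries(((1e-5, 0, 100),), 600)
        gram = simulate_sensorgram(taals, 100.0, s, timestep_s=1.0)
        inj = gram.time_s <= 100
        assert np.all(np.diff(gram.response_ru[inj]) >= -1e-9)
        peak = gram.response_ru[inj].max()
        assert gram.response_ru[-1] < peak

    def test_conservation_bound(self):
        s = DEFAULT_SINGLE_CYCLE_SCHEDULE
        gram = simulate_sensorgram(DAALT_RATES, 100.0, s, timestep_s=2.0)
        assert np.all(gram.response_ru >= -1e-9)
        assert np.all(gram.response_ru <= 100.0 + 1e-6)

    def test_saturation_at_high_concentration(self):
        rates = TwoStateRates(1e4, 1e-3, 0.0, 0.0)  # K_D = 1e-7 M
        s = InjectionSeries(((1e-4, 0, 5000),), 5000)  # C = 1000 x K_D
        gram = simulate_sensorgram(rates, 100.0, s)
        assert gram.response_ru[-1] == pytest.approx(100.0, rel=1e-2)

    def test_steady_state_matches_derived_equilibrium(self):
        """Long-time response fraction equals C / (C + K_D)."""
        rates = TwoStateRates(1e3, 1e-2, 2e-3, 1e-3)
        kd = derive_equilibrium(rates).K_D
        c = 2.0 * kd
        s = InjectionSeries(((c, 0, 2e5),), 2e5)
        gram = simulate_sensorgram(rates, 100.0, s, timestep_s=1000.0)
        assert gram.response_ru[-1] / 100.0 == pytest.approx(c / (c + kd), rel=1e-3)

    def test_langmuir_closed_form_in_two_state_limit(self):
        """k_a2, k_d2 -> 0 reduces to R(t) = R_eq (1 - exp(-(k_a1 C + k_d1) t))."""
        ka1, kd1, c, rmax = 1e3, 5e-3, 1e-6, 80.0
        rates = TwoStateRates(ka1, kd1, 0.0, 0.0)
        s = InjectionSeries(((c, 0, 400),), 400)
        gram = simulate_sensorgram(rates, rmax, s, timestep_s=1.0)
        kobs = ka1 * c + kd1
        r_eq = rmax * ka1 * c / kobs
        analytic = r_eq * (1.0 - np.exp(-kobs * gram.time_s))
        np.testing.assert_allclose(gram.response_ru, analytic, atol=1e-5 * rmax)

    def test_no_regeneration_state_carries_over(self):
        s = InjectionSeries(((1e-6, 0, 200), (1e-5, 300, 500)), 800)
        gram = simulate_sensorgram(DAALT_RATES, 100.0, s, timestep_s=1.0)
        start_second = np.searchsorted(gram.time_s, 300.0)
        assert gram.response_ru[start_second] > 0.0


class TestFit:
    def test_noiseless_identity_fit(self):
        gram = simulate_sensorgram(DAALT_RATES, 100.0, DEFAULT_SINGLE_CYCLE_SCHEDULE, timestep_s=2.0)
        fit = fit_two_state([(gram, DEFAULT_SINGLE_CYCLE_SCHEDULE)], DAALT_RATES, 100.0, timestep_s=2.0)
        assert fit.success
        assert fit.rss < 1e-10
        np.testing.assert_allclose(fit.rates.as_array(), DAALT_RATES.as_array(), rtol=1e-6)

    def test_noisy_recovery_from_perturbed_guess(self):
        from allopep.synthetic_data import SensorgramSpec, generate_sensorgram
        spec = SensorgramSpec(DAALT_RATES, 100.0, DEFAULT_SINGLE_CYCLE_SCHEDULE,
                              noise_sd=1.0, timestep_s=2.0, seed=5)
        gram = generate_sensorgram(spec)
        guess = TwoStateRates(*(DAALT_RATES.as_array() * [2.0, 0.5, 2.0, 0.5]))
        fit = fit_two_state([(gram, DEFAULT_SINGLE_CYCLE_SCHEDULE)], guess, 150.0, timestep_s=2.0)
        rel = np.abs(fit.rates.as_array() / DAALT_RATES.as_array() - 1.0)
        assert rel.max() < 0.10
        assert fit.derived.K_D == pytest.approx(derive_equilibrium(DAALT_RATES).K_D, rel=0.10)

    def test_global_fit_beats_or_matches_separate(self):
        """On mutually consistent curves the shared-parameter RSS is no
        worse than the sum of individually fitted RSS (plus tolerance)."""
        s1 = InjectionSeries(((1e-6, 0, 300),), 2000)
        s2 = InjectionSeries(((1e-5, 0, 300),), 2000)
        g1 = simulate_sensorgram(DAALT_RATES, 100.0, s1, timestep_s=5.0)
        g2 = simulate_sensorgram(DAALT_RATES, 100.0, s2, timestep_s=5.0)
        joint = fit_two_state([(g1, s1), (g2, s2)], DAALT_RATES, 100.0, timestep_s=5.0)
        f1 = fit_two_state([(g1, s1)], DAALT_RATES, 100.0, timestep_s=5.0)
        f2 = fit_two_state([(g2, s2)], DAALT_RATES, 100.0, timestep_s=5.0)
        assert joint.rss <= f1.rss + f2.rss + 1e-8

    def test_std_errors_reported(self):
        gram = simulate_sensorgram(DAALT_RATES, 100.0, DEFAULT_SINGLE_CYCLE_SCHEDULE, timestep_s=2.0)
        fit = fit_two_state([(gram, DEFAULT_SINGLE_CYCLE_SCHEDULE)], DAALT_RATES, 100.0, timestep_s=2.0)
        assert set(fit.std_errors) == {"k_a1", "k_d1", "k_a2", "k_d2", "rmax"}
        assert all(np.isfinite(v) for v in fit.std_errors.values())


class TestAtpCompetition:
    def test_daalt_flagged(self):
        assert atp_competition_call(0.47e-6, 37e-6) == POSSIBLE_COMPETITION

    @pytest.mark.parametrize(
        "without, with_atp",
        [(1.4e-6, 3.3e-6), (8.0e-6, 61e-6), (98e-6, 61e-6)],
        ids=["TAALS", "LAALS", "YAALQ"],
    )
    def test_within_tenfold_not_significant(self, without, with_atp):
        assert atp_competition_call(without, with_atp) == NOT_SIGNIFICANT

    def test_equal_values_fold_one(self):
        assert atp_competition_call(1e-6, 1e-6) == NOT_SIGNIFICANT

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            atp_competition_call(0.0, 1e-6)


def test_sensorgram_csv_round_trip(tmp_path):
    s = InjectionSeries(((1e-6, 0, 100),), 300)
    gram = simulate_sensorgram(DAALT_RATES, 50.0, s)
    path = tmp_path / "gram.csv"
    gram.write_csv(path)
    back = Sensorgram.read_csv(path)
    np.testing.assert_allclose(back.response_ru, gram.response_ru)
    np.testing.assert_allclose(back.time_s, gram.time_s)
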