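import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_fit
from oculorhythm.cosinor import (OMEGA, coeffs_to_polar, diurnal_variation_test,
                                 evaluate_sinusoid, fit_individual, fit_population,
                                 normalize_to_mesor, polar_to_coeffs, wrap_half_day)
from oculorhythm.studies import grid_search_cosinor
from oculorhythm.synthetic import default_truth, generate_cohort, noise_free

EPOCH_TIMES = np.array([-15.0, -12.0, -4.0, -3.0, -2.0, -1.0, 0.0, 1.0])


def sinusoid(t, m, a, acro):
    return m + a * np.sin(OMEGA * (np.asarray(t, float) + 6.0 - acro))


class TestEvaluate:
    def test_flat_rhythm(self):
        fit = make_fit(10.0, 0.0, 6.0)
        t = np.linspace(-12, 12, 7)
        assert evaluate_sinusoid(fit, t) == pytest.approx([10.0] * 7)

    def test_peak_and_trough(self):
        fit = make_fit(2.0, 1.5, -9.0)
        assert evaluate_sinusoid(fit, fit.acrophase) == pytest.approx(3.5)
        assert evaluate_sinusoid(fit, fit.acrophase + 12.0) == pytest.approx(0.5)

    @given(st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_periodicity(self, t):
        fit = make_fit(1.0, 2.0, 3.0)
        assert evaluate_sinusoid(fit, t) == pytest.approx(
            evaluate_sinusoid(fit, t + 24.0), abs=1e-9)


class TestPolarConversion:
    @pytest.mark.parametrize("bs, bc, amp, acro", [
        (1.0, 0.0, 1.0, 6.0),   # pure sine peaks 6 h after the origin
        (0.0, 1.0, 1.0, 0.0),   # pure cosine peaks at the origin
        (0.0, -1.0, 1.0, 12.0),  # trough at origin -> peak half a day away
    ])
    def test_cardinal_directions(self, bs, bc, amp, acro):
        a, phi = coeffs_to_polar(bs, bc)
        assert a == pytest.approx(amp)
        assert phi == pytest.approx(acro)

    @given(st.floats(1e-3, 10), st.floats(-11.99, 12))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, amp, acro):
        bs, bc = polar_to_coeffs(amp, acro)
        a2, acro2 = coeffs_to_polar(bs, bc)
        assert a2 == pytest.approx(amp, rel=1e-9)
        assert wrap_half_day(acro2 - acro) == pytest.approx(0.0, abs=1e-9)


class TestFitIndividual:
    def test_exact_recovery_noise_free(self):
        y = sinusoid(EPOCH_TIMES, 10.0, 2.0, -9.0)
        fit = fit_individual(EPOCH_TIMES, y)
        assert fit.mesor == pytest.approx(10.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.acrophase == pytest.approx(-9.0, abs=1e-9)

    def test_log_scale_recovery(self):
        y = np.exp(sinusoid(EPOCH_TIMES, 0.87, 3.155, 3.99))
        fit = fit_individual(EPOCH_TIMES, y, log_scale=True)
        assert fit.mesor == pytest.approx(0.87, abs=1e-9)
        assert fit.amplitude == pytest.approx(3.155, abs=1e-9)

    def test_constant_series_degenerate(self):
        fit = fit_individual(EPOCH_TIMES, np.full(8, 4.2))
        assert fit.mesor == pytest.approx(4.2)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert fit.acrophase == 6.0
        assert fit.degenerate

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            fit_individual([0, 1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            fit_individual([0, 0, 24, 24], [1, 2, 3, 4])  # < 3 distinct mod 24

    @given(st.floats(-12, 12), st.floats(-5, 5))
    @settings(max_examples=30, deadline=None)
    def test_equivariance(self, delta, offset):
        rng = np.random.default_rng(7)
        y = sinusoid(EPOCH_TIMES, 5.0, 1.2, 2.5) + rng.normal(0, 0.1, 8)
        base = fit_individual(EPOCH_TIMES, y)
        shifted = fit_individual(EPOCH_TIMES + delta, y)
        assert shifted.mesor == pytest.approx(base.mesor, abs=1e-8)
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-8)
        assert wrap_half_day(shifted.acrophase - base.acrophase - delta) == \
            pytest.approx(0.0, abs=1e-8)
        raised = fit_individual(EPOCH_TIMES, y + offset)
        assert raised.mesor == pytest.approx(base.mesor + offset, abs=1e-8)
        assert raised.amplitude == pytest.approx(base.amplitude, abs=1e-8)

    def test_matches_grid_search_on_noisy_series(self, rng):
        y = sinusoid(EPOCH_TIMES, 3.0, 1.0, -8.0) + rng.normal(0, 0.3, 8)
        fit = fit_individual(EPOCH_TIMES, y)
        gm, ga, gacro, grss = grid_search_cosinor(EPOCH_TIMES, y, acro_step=0.01)
        fit_rss = float(np.sum((y - evaluate_sinusoid(fit, EPOCH_TIMES)) ** 2))
        assert fit_rss <= grss + 1e-9
        assert abs(wrap_half_day(fit.acrophase - gacro)) <= 0.01


class TestFitPopulation:
    def _slice(self, cohort, param="AL", season="W1"):
        return cohort.slice(param, season)

    def test_single_participant_equals_individual(self):
        truth = default_truth(parameters=("AL",), seasons=("W1",), n_participants=24, seed=4)
        cohort, _ = generate_cohort(truth)
        one = cohort.measurements[cohort.measurements["participant_id"] == "P01"]
        pop, ind = fit_population(one)
        assert len(ind) == 1
        assert pop.mesor == pytest.approx(ind[0].mesor)
        assert pop.acrophase == pytest.approx(ind[0].acrophase)
        assert pop.scope == "population"

    def test_noise_free_cohort_recovers_truth_exactly(self):
        truth = noise_free(default_truth(parameters=("AL",), seasons=("W1",),
                                         n_participants=6))
        cohort, _ = generate_cohort(truth)
        pop, _ = fit_population(self._slice(cohort))
        assert pop.mesor == pytest.approx(23.92, abs=1e-8)
        assert pop.amplitude == pytest.approx(0.019, abs=1e-8)
        assert pop.acrophase == pytest.approx(-8.79, abs=1e-6)

    def test_cloned_cohort_equals_source_individual(self):
        rng = np.random.default_rng(11)
        y = sinusoid(EPOCH_TIMES, 23.9, 0.02, -9.0) + rng.normal(0, 0.004, 8)
        frames = []
        for pid in ("A", "B", "C"):
            frames.append(pd.DataFrame({
                "participant_id": pid, "t_rel": EPOCH_TIMES, "value": y}))
        data = pd.concat(frames, ignore_index=True)
        pop, ind = fit_population(data)
        assert pop.mesor == pytest.approx(ind[0].mesor, abs=1e-6)
        assert pop.amplitude == pytest.approx(ind[0].amplitude, abs=1e-6)
        assert pop.acrophase == pytest.approx(ind[0].acrophase, abs=1e-5)

    def test_bootstrap_ci_brackets_point_estimate(self):
        truth = default_truth(parameters=("AL",), seasons=("W1",),
                              n_participants=24, seed=9)
        cohort, _ = generate_cohort(truth)
        pop, _ = fit_population(self._slice(cohort), ci=True, n_boot=200, seed=1)
        for q in ("mesor", "amplitude", "acrophase"):
            lo, hi = pop.ci[q]
            assert lo < hi
        lo, hi = pop.ci["mesor"]
        assert lo < pop.mesor < hi


class TestDiurnalVariation:
    def test_strong_rhythm_detected(self):
        truth = default_truth(parameters=("MEL",), seasons=("W1",),
                              n_participants=24, seed=2)
        cohort, _ = generate_cohort(truth)
        res = diurnal_variation_test(cohort.slice("MEL", "W1"), log_scale=True)
        assert res.p_value < 0.001
        assert res.statistic > 0

    def test_permutation_agrees_with_analytic(self):
        truth = default_truth(parameters=("IOP",), seasons=("W1",),
                              n_participants=12, seed=3)
        cohort, _ = generate_cohort(truth)
        data = cohort.slice("IOP", "W1")
        res = diurnal_variation_test(data, n_perm=499, seed=5)
        assert res.p_permutation is not None
        assert abs(res.p_permutation - res.p_value) <= 0.02

    def test_requires_multiple_participants_and_epochs(self):
        df = pd.DataFrame({
            "participant_id": ["A"] * 8, "epoch_label": list("abcdefgh"),
            "value": np.arange(8.0)})
        with pytest.raises(ValueError):
            diurnal_variation_test(df)


class TestNormalization:
    def test_constant_series_maps_to_zero(self):
        fit = fit_individual(EPOCH_TIMES, np.full(8, 3.3))
        assert normalize_to_mesor(np.full(8, 3.3), fit) == pytest.approx([0.0] * 8)

    def test_refit_preserves_rhythm(self, rng):
        y = sinusoid(EPOCH_TIMES, 13.4, 2.8, -10.1) + rng.normal(0, 0.5, 8)
        fit = fit_individual(EPOCH_TIMES, y)
        z = normalize_to_mesor(y, fit)
        refit = fit_individual(EPOCH_TIMES, z)
        assert refit.mesor == pytest.approx(0.0, abs=1e-9)
        assert refit.amplitude == pytest.approx(fit.amplitude, abs=1e-9)
        assert refit.acrophase == pytest.approx(fit.acrophase, abs=1e-9)
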