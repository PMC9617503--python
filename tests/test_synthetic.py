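import numpy as np
import pytest

from oculorhythm.cosinor import OMEGA
from oculorhythm.io_model import MEL_EPOCH_LABELS
from oculorhythm.synthetic import (GrowthTruth, SimulationTruth, default_truth,
                                   generate_cohort, generate_growth_cohort,
                                   noise_free, noise_sd_for_r2)


class TestGenerateCohort:
    def test_noise_free_series_lie_on_population_sinusoid(self):
        truth = noise_free(default_truth(parameters=("AL", "MEL"), seasons=("W1",),
                                         n_participants=4))
        cohort, _ = generate_cohort(truth)
        al = cohort.slice("AL", "W1")
        expected = 23.92 + 0.019 * np.sin(OMEGA * (al["t_rel"].to_numpy() + 6.0 + 8.79))
        assert np.max(np.abs(al["value"].to_numpy() - expected)) == 0.0
        mel = cohort.slice("MEL", "W1")
        log_expected = 0.87 + 3.155 * np.sin(OMEGA * (mel["t_rel"].to_numpy() + 6.0 - 3.99))
        assert np.max(np.abs(np.log(mel["value"].to_numpy()) - log_expected)) < 1e-12

    def test_same_seed_bit_identical(self):
        truth = default_truth(parameters=("AL",), n_participants=6, seed=42)
        c1, t1 = generate_cohort(truth)
        c2, t2 = generate_cohort(truth)
        assert c1.measurements.equals(c2.measurements)
        assert c1.participants.equals(c2.participants)
        assert t1.equals(t2)

    def test_different_seed_differs(self):
        a, _ = generate_cohort(default_truth(parameters=("AL",), n_participants=6, seed=1))
        b, _ = generate_cohort(default_truth(parameters=("AL",), n_participants=6, seed=2))
        assert not a.measurements["value"].equals(b.measurements["value"])

    def test_melatonin_positive_and_sampled_at_seven_epochs(self):
        truth = default_truth(parameters=("MEL",), n_participants=10, seed=3)
        cohort, _ = generate_cohort(truth)
        mel = cohort.slice("MEL", "W1")
        assert (mel["value"] > 0).all()
        assert set(mel["epoch_label"]) == set(MEL_EPOCH_LABELS)
        per_subject = mel.groupby("participant_id").size()
        assert (per_subject == len(MEL_EPOCH_LABELS)).all()

    def test_truth_table_matches_generated_subjects(self):
        truth = default_truth(parameters=("AL",), seasons=("W1", "S"),
                              n_participants=5, seed=8)
        cohort, truth_df = generate_cohort(truth)
        assert len(truth_df) == 5 * 2  # participant x season
        assert set(truth_df["participant_id"]) == set(cohort.participants["id"])
        # subject effects persist across seasons: amplitude deviations from
        # the season truth are identical in W1 and S
        wide = truth_df.pivot(index="participant_id", columns="season",
                              values="amplitude")
        dev_w = wide["W1"] - 0.019
        dev_s = wide["S"] - 0.022
        assert np.allclose(dev_w, dev_s, atol=1e-12)

    def test_empty_configuration_rejected(self):
        with pytest.raises(ValueError):
            SimulationTruth(seasons=())
        truth = default_truth(parameters=("AL",), n_participants=1)
        with pytest.raises(ValueError, match="n >= 2"):
            generate_cohort(truth)


class TestGrowthCohort:
    def test_truth_intervals_exactly_additive(self):
        _, truth = generate_growth_cohort(GrowthTruth(n_participants=16, seed=4))
        assert np.allclose(truth["dal_w1_s"] + truth["dal_s_w2"],
                           truth["dal_w1_w2"], atol=0.0)

    def test_null_growth_configuration(self):
        gtruth = GrowthTruth(n_participants=8, mean_dal_w1_s=0.0, sd_dal_w1_s=0.0,
                             mean_dal_s_w2=0.0, sd_dal_s_w2=0.0,
                             slope_cht=0.0, intercept_cht=0.0, noise_cht_sd=0.0,
                             slope_phase=0.0, intercept_phase=0.0,
                             noise_phase_sd=0.0, seed=6)
        _, truth = generate_growth_cohort(gtruth)
        assert truth["dal_w1_s"].abs().max() == 0.0
        assert truth["al_phase_shift"].abs().max() == 0.0

    def test_noise_sd_for_r2(self):
        sd = noise_sd_for_r2(slope=2.0, sd_x=1.5, r2=0.5)
        assert sd == pytest.approx(3.0)
        with pytest.raises(ValueError):
            noise_sd_for_r2(1.0, 1.0, 1.5)

    def test_deterministic(self):
        g = GrowthTruth(n_participants=6, seed=9)
        c1, t1 = generate_growth_cohort(g)
        c2, t2 = generate_growth_cohort(g)
        assert c1.measurements.equals(c2.measurements)
        assert t1.equals(t2)
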