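import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oculorhythm.season import (circular_diff, compare_seasons, holm_adjust,
                                phase_relation)


class TestCircularDiff:
    def test_reference_axial_length_shift(self):
        # summer (-9.81) minus winter (-8.79) acrophase: a 1.02-h advance
        assert circular_diff(-9.81, -8.79) == pytest.approx(-1.02)

    def test_identity_and_wrap(self):
        assert circular_diff(5.0, 5.0) == 0.0
        assert circular_diff(11.0, -11.0) == pytest.approx(-2.0)
        assert circular_diff(-11.0, 11.0) == pytest.approx(2.0)

    @given(st.floats(-12, 12), st.floats(-12, 12))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_up_to_wrap(self, a, b):
        d1, d2 = circular_diff(a, b), circular_diff(b, a)
        if abs(d1) != 12.0:
            assert d1 == pytest.approx(-d2, abs=1e-9)
        else:
            assert d1 == 12.0 and d2 == 12.0

    @given(st.floats(-12, 12), st.floats(-12, 12))
    @settings(max_examples=50, deadline=None)
    def test_period_invariance(self, a, b):
        # equality on the circle (the +/-12 boundary itself is fp-sensitive)
        d = circular_diff(a + 24, b) - circular_diff(a, b)
        assert min(abs(d), 24 - abs(d)) == pytest.approx(0.0, abs=1e-9)


class TestPhaseRelation:
    def test_winter_al_cht_near_exact_antiphase(self):
        rel = phase_relation(3.10, -8.79)  # ChT vs AL winter acrophases
        assert rel.acrophase_separation == pytest.approx(11.89)
        assert rel.antiphase_distance == pytest.approx(0.11)

    def test_identical_acrophases(self):
        rel = phase_relation(4.0, 4.0)
        assert rel.inphase_distance == 0.0
        assert rel.antiphase_distance == 12.0

    def test_exact_antiphase(self):
        rel = phase_relation(-6.0, 6.0)
        assert rel.antiphase_distance == pytest.approx(0.0)

    @given(st.floats(-12, 12), st.floats(-12, 12))
    @settings(max_examples=50, deadline=None)
    def test_distances_complementary(self, a, b):
        rel = phase_relation(a, b)
        assert rel.antiphase_distance + rel.inphase_distance == pytest.approx(12.0)
        assert phase_relation(a + 24, b).antiphase_distance == \
            pytest.approx(rel.antiphase_distance, abs=1e-9)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]) == pytest.approx([0.03])

    def test_step_down_example(self):
        assert holm_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.04, 0.04])

    def test_order_restored(self):
        adj = holm_adjust([0.04, 0.01, 0.02])
        assert adj == pytest.approx([0.04, 0.03, 0.04])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10))
    @settings(max_examples=100, deadline=None)
    def test_dominated_by_bonferroni(self, ps):
        adj = holm_adjust(ps)
        m = len(ps)
        assert np.all(adj <= np.minimum(np.asarray(ps) * m, 1.0) + 1e-12)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)


def _fits_frame(season, values_by_pid):
    rows = []
    for pid, (m, a, acro) in values_by_pid.items():
        rows.append({"participant_id": pid, "parameter": "AL", "season": season,
                     "mesor": m, "amplitude": a, "acrophase": acro})
    return pd.DataFrame(rows)


class TestCompareSeasons:
    def test_identical_seasons_degenerate(self):
        vals = {f"P{i}": (23.9 + 0.01 * i, 0.02, -9.0 + 0.1 * i) for i in range(6)}
        frame = _fits_frame("W1", vals)
        result = compare_seasons(frame, frame.assign(season="S"))
        assert (result["delta"] == 0.0).all()
        assert (result["p_holm"] == 1.0).all()
        assert result["degenerate"].all()

    def test_detects_injected_advance(self, rng):
        winter = {f"P{i}": (23.9, 0.02, -9.0 + rng.normal(0, 0.3)) for i in range(24)}
        summer = {pid: (m, a, acro - 1.0 + rng.normal(0, 0.2))
                  for pid, (m, a, acro) in winter.items()}
        result = compare_seasons(_fits_frame("W1", winter), _fits_frame("S", summer))
        row = result[result["quantity"] == "acrophase"].iloc[0]
        assert row["delta"] == pytest.approx(-1.0, abs=0.25)
        assert row["p_holm"] < 0.01

    def test_requires_three_pairs(self):
        vals = {"A": (1, 1, 0), "B": (1, 1, 0)}
        with pytest.raises(ValueError):
            compare_seasons(_fits_frame("W1", vals), _fits_frame("S", vals))
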