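"""MESS similarity, novelty maps, risk tiers and envelope drift."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import enmkit as ek
from enmkit.errors import AlignmentError, DegenerateReferenceError
from enmkit.novelty import RISK_HIGH, RISK_MODERATE, RISK_RELIABLE


def brute_force_similarity(value, reference):
    """Direct transcription of the piecewise MESS definition."""
    ref = sorted(reference)
    lo, hi = ref[0], ref[-1]
    f = 100.0 * sum(r < value for r in ref) / len(ref)
    if f == 0:
        return 100.0 * (value - lo) / (hi - lo)
    if f <= 50:
        return 2.0 * f
    if f < 100:
        return 2.0 * (100.0 - f)
    return 100.0 * (hi - value) / (hi - lo)


class TestMessSimilarity:
    def test_median_scores_100(self):
        ref = np.arange(1, 11)  # value 5.5: exactly half the reference below
        assert ek.mess_similarity(5.5, ref) == pytest.approx(100.0)

    def test_below_range_is_negative_linear(self):
        assert ek.mess_similarity(0.0, np.arange(1, 11)) == pytest.approx(
            100.0 * (0 - 1) / 9)

    def test_lower_tail_branch(self):
        # 2 of 10 reference values below 2.5 -> f = 20 -> similarity 40
        assert ek.mess_similarity(2.5, np.arange(1, 11)) == pytest.approx(40.0)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(DegenerateReferenceError):
            ek.mess_similarity(1.0, [2.0, 2.0, 2.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(-20, 20),
           st.lists(st.integers(-5, 5), min_size=2, max_size=25).filter(
               lambda v: len(set(v)) >= 2))
    def test_matches_piecewise_definition(self, value, reference):
        got = ek.mess_similarity(value, np.array(reference, dtype=float))
        assert got == pytest.approx(brute_force_similarity(value, reference))


class TestClassifyRisk:
    @pytest.mark.parametrize("value, tier", [
        (0.5, RISK_RELIABLE), (100.0, RISK_RELIABLE),
        (0.0, RISK_MODERATE), (-5.0, RISK_MODERATE), (-10.0, RISK_MODERATE),
        (-10.0001, RISK_HIGH), (-12.0, RISK_HIGH),
    ])
    def test_published_cuts(self, value, tier):
        assert ek.classify_risk(value) == tier

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(-1e6, 1e6, allow_nan=False))
    def test_every_value_gets_exactly_one_tier(self, value):
        assert ek.classify_risk(value) in (RISK_RELIABLE, RISK_MODERATE, RISK_HIGH)


class TestMessMap:
    def test_within_range_projection_nonnegative(self, small_stack):
        env = ek.extract_env(small_stack, pd.DataFrame({
            "x": np.random.default_rng(0).uniform(0, 60, 200),
            "y": np.random.default_rng(1).uniform(0, 60, 200)}), drop_invalid=True)
        envelope = ek.ReferenceEnvelope.from_table(env, ["bio16", "bio15"])
        nov = ek.mess_map(envelope, small_stack)
        assert nov.mess.shape == small_stack.grid.shape
        # minimum property: mess never exceeds any single variable's similarity
        for i, j in [(0, 0), (10, 40), (59, 59)]:
            for v in nov.variables:
                assert nov.mess[i, j] <= ek.mess_similarity(
                    small_stack[v][i, j], envelope.values[v]) + 1e-9
        # envelope records score themselves as non-novel
        self_sim = [ek.mess_similarity(v, envelope.values["bio16"])
                    for v in envelope.values["bio16"]]
        assert min(self_sim) >= 0.0

    def test_shifted_layer_becomes_most_dissimilar(self, small_stack):
        env = ek.extract_env(small_stack, pd.DataFrame({
            "x": np.random.default_rng(2).uniform(0, 60, 300),
            "y": np.random.default_rng(3).uniform(0, 60, 300)}), drop_invalid=True)
        envelope = ek.ReferenceEnvelope.from_table(env, ["bio16", "bio15"])
        shift = 20 * small_stack["bio16"].std()
        future = ek.gen_future_stack(small_stack, {"bio16": (shift, 1.0)})
        nov = ek.mess_map(envelope, future)
        assert (nov.mess < 0).all()
        assert (nov.mod == nov.variables.index("bio16")).all()
        assert (nov.risk == RISK_HIGH).all()

    def test_matches_per_cell_brute_force(self):
        rng = np.random.default_rng(13)
        grid = ek.GridSpec(20, 20, 1.0)
        stack = ek.PredictorStack(grid, {
            "a": rng.normal(size=grid.shape), "b": rng.normal(size=grid.shape)})
        envelope = ek.ReferenceEnvelope({
            "a": rng.normal(size=40), "b": rng.normal(size=40)})
        nov = ek.mess_map(envelope, stack)
        for i in range(20):
            for j in range(20):
                sims = [brute_force_similarity(stack[v][i, j],
                                               envelope.values[v])
                        for v in nov.variables]
                assert nov.mess[i, j] == pytest.approx(min(sims))
                assert nov.mod[i, j] == int(np.argmin(sims))

    def test_missing_layer_rejected(self, small_stack):
        envelope = ek.ReferenceEnvelope({"zz": np.arange(5.0)})
        with pytest.raises(AlignmentError):
            ek.mess_map(envelope, small_stack)


class TestEnvelopeShift:
    def test_identical_stacks_have_zero_displacement(self, small_stack):
        report = ek.envelope_shift(small_stack, small_stack.copy(),
                                   ["bio16", "bio15"]).set_index("variable")
        assert report.loc["bio16", "mean_displacement"] == 0.0
        assert report.loc["bio16", "overlap"] == pytest.approx(1.0)
        assert report.loc["bio16", "direction"] == "none"

    def test_translation_recovered_exactly(self, small_stack):
        future = ek.gen_future_stack(small_stack, {"bio16": (50.0, 1.0)})
        report = ek.envelope_shift(small_stack, future,
                                   ["bio16"]).set_index("variable")
        assert report.loc["bio16", "mean_displacement"] == pytest.approx(50.0)
        assert report.loc["bio16", "median_displacement"] == pytest.approx(
            50.0, abs=1e-9)
        assert report.loc["bio16", "direction"] == "rightward"

    def test_overlap_symmetric(self, small_stack):
        future = ek.gen_future_stack(small_stack, {"bio15": (2.0, 1.2)})
        fwd = ek.envelope_shift(small_stack, future, ["bio15"])
        rev = ek.envelope_shift(future, small_stack, ["bio15"])
        assert fwd["overlap"].iloc[0] == pytest.approx(rev["overlap"].iloc[0])
        assert rev["direction"].iloc[0] == "leftward"
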