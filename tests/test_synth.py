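"""Synthetic generators: determinism, moments, ground-truth structure."""

import numpy as np
import pytest

import enmkit as ek
from enmkit.errors import ConfigError
from enmkit.synth import sample_presences


GRID = ek.GridSpec(200, 200, 1.0)


class TestPredictorStack:
    def test_same_seed_is_bit_identical(self):
        specs = [ek.LayerSpec("a", 5.0, 1.0, 4.0), ek.LayerSpec("b", 0.0, 2.0, 6.0)]
        s1 = ek.gen_predictor_stack(GRID, specs, seed=42)
        s2 = ek.gen_predictor_stack(GRID, specs, seed=42)
        for name in s1.names:
            np.testing.assert_array_equal(s1[name], s2[name])

    def test_requested_moments_recovered(self):
        stack = ek.gen_predictor_stack(
            GRID, [ek.LayerSpec("v", 10.0, 2.0, 5.0)], seed=1)
        assert abs(stack["v"].mean() - 10.0) < 0.5
        assert abs(stack["v"].std() - 2.0) < 0.5

    def test_uncorrelated_layers_nearly_independent(self):
        # modest smoothing keeps enough effective samples for a tight bound
        stack = ek.gen_predictor_stack(
            GRID, [ek.LayerSpec("a", 0, 1, 2.0), ek.LayerSpec("b", 0, 1, 2.0)],
            correlation=np.eye(2), seed=7)
        r = np.corrcoef(stack["a"].ravel(), stack["b"].ravel())[0, 1]
        assert abs(r) < 0.15

    def test_imposed_cross_correlation(self):
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        stack = ek.gen_predictor_stack(
            GRID, [ek.LayerSpec("a", 0, 1, 5.0), ek.LayerSpec("b", 0, 1, 5.0)],
            correlation=corr, seed=7)
        r = np.corrcoef(stack["a"].ravel(), stack["b"].ravel())[0, 1]
        assert abs(r - 0.8) < 0.15

    @pytest.mark.parametrize("corr, msg", [
        (np.array([[1.0, 0.99], [0.5, 1.0]]), "symmetric"),
        (np.array([[1.0, 2.0], [2.0, 1.0]]), "PSD"),
        (np.array([[2.0, 0.0], [0.0, 1.0]]), "diagonal"),
    ])
    def test_bad_correlation_rejected(self, corr, msg):
        specs = [ek.LayerSpec("a", 0, 1, 2.0), ek.LayerSpec("b", 0, 1, 2.0)]
        with pytest.raises(ConfigError, match=msg):
            ek.gen_predictor_stack(GRID, specs, correlation=corr, seed=0)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigError, match="duplicate"):
            ek.gen_predictor_stack(
                GRID, [ek.LayerSpec("a", 0, 1, 2.0), ek.LayerSpec("a", 1, 1, 2.0)],
                seed=0)


class TestVirtualSpecies:
    def test_gaussian_response_closed_form(self, small_stack):
        cfg = ek.VirtualSpeciesConfig(
            responses={"bio16": ek.Response("gaussian", 880.0, 30.0)})
        suit = ek.gen_virtual_species(small_stack, cfg)
        expected = np.exp(-0.5 * ((small_stack["bio16"] - 880.0) / 30.0) ** 2)
        np.testing.assert_allclose(suit, expected)
        # one breadth from the optimum the response is exactly exp(-1/2)
        r = ek.Response("gaussian", 880.0, 30.0)
        assert r.evaluate(np.array([910.0]))[0] == pytest.approx(np.exp(-0.5))
        assert r.evaluate(np.array([880.0]))[0] == 1.0

    def test_product_rule_peaks_at_joint_optimum(self, small_stack):
        cfg = ek.VirtualSpeciesConfig(responses={
            "bio16": ek.Response("gaussian", 880.0, 30.0),
            "bio15": ek.Response("gaussian", 65.0, 3.0),
        })
        suit = ek.gen_virtual_species(small_stack, cfg)
        parts = [np.exp(-0.5 * ((small_stack["bio16"] - 880) / 30) ** 2),
                 np.exp(-0.5 * ((small_stack["bio15"] - 65) / 3) ** 2)]
        np.testing.assert_allclose(suit, parts[0] * parts[1])

    def test_flat_responses_constant(self, small_stack):
        cfg = ek.VirtualSpeciesConfig(responses={"bio16": ek.Response("flat")})
        suit = ek.gen_virtual_species(small_stack, cfg)
        assert np.all(suit == 1.0)

    def test_unknown_variable_rejected(self, small_stack):
        cfg = ek.VirtualSpeciesConfig(
            responses={"nope": ek.Response("gaussian", 0, 1)})
        with pytest.raises(ConfigError, match="nope"):
            ek.gen_virtual_species(small_stack, cfg)


@pytest.fixture(scope="module")
def true_suit(small_stack):
    cfg = ek.VirtualSpeciesConfig(
        responses={"bio16": ek.Response("gaussian", 876.0, 30.0)})
    return ek.gen_virtual_species(small_stack, cfg)


class TestClassifierOutput:

    def test_perfect_targets_reproduce_truth(self, true_suit, small_stack):
        spec = ek.ClassifierSpec(fine_factor=2, target_precision=1.0,
                                 target_recall=1.0, prevalence=0.2, seed=3)
        pred, truth = ek.gen_classifier_output(true_suit, small_stack.grid, spec)
        np.testing.assert_array_equal(pred.labels, truth.labels)
        assert pred.grid.cell_size == small_stack.grid.cell_size / 2

    def test_targets_recovered_within_binomial_noise(self):
        # large instance so realized rates concentrate near targets
        grid = ek.GridSpec(200, 200, 1.0)
        stack = ek.gen_predictor_stack(grid, [ek.LayerSpec("v", 0, 1, 5.0)], seed=9)
        suit = ek.gen_virtual_species(stack, ek.VirtualSpeciesConfig(
            responses={"v": ek.Response("gaussian", 0.0, 1.0)}))
        spec = ek.ClassifierSpec(fine_factor=1, target_precision=0.9,
                                 target_recall=0.9, prevalence=0.25, seed=4)
        pred, truth = ek.gen_classifier_output(suit, grid, spec)
        m = ek.segmentation_metrics(pred, truth)
        assert truth.positive_count == pytest.approx(10_000, abs=5)
        assert m.recall == pytest.approx(0.9, abs=0.02)
        assert m.precision == pytest.approx(0.9, abs=0.02)

    def test_zero_targets_rejected(self):
        with pytest.raises(ConfigError):
            ek.ClassifierSpec(target_precision=0.0)


class TestFutureStack:
    def test_identity_shift(self, small_stack):
        out = ek.gen_future_stack(small_stack,
                                  {"bio16": (0.0, 1.0), "bio15": (0.0, 1.0)})
        for name in small_stack.names:
            np.testing.assert_array_equal(out[name], small_stack[name])

    def test_pure_translation(self, small_stack):
        out = ek.gen_future_stack(small_stack, {"bio16": (50.0, 1.0)})
        np.testing.assert_allclose(out["bio16"] - small_stack["bio16"], 50.0)
        np.testing.assert_array_equal(out["bio15"], small_stack["bio15"])

    def test_scale_changes_spread(self):
        grid = ek.GridSpec(200, 200, 1.0)
        stack = ek.gen_predictor_stack(grid, [ek.LayerSpec("v", 0, 2, 5.0)], seed=5)
        out = ek.gen_future_stack(stack, {"v": (0.0, 1.5)})
        ratio = out["v"].std() / stack["v"].std()
        assert ratio == pytest.approx(1.5, abs=0.05)

    def test_unknown_variable_rejected(self, small_stack):
        with pytest.raises(ConfigError):
            ek.gen_future_stack(small_stack, {"missing": (1.0, 1.0)})


class TestSamplePresences:
    def test_density_tracks_suitability(self):
        grid = ek.GridSpec(100, 100, 1.0)
        suit = np.zeros(grid.shape)
        suit[:50] = 0.9   # northern half is 9x more attractive
        suit[50:] = 0.1
        pts = sample_presences(suit, grid, 2000, seed=8)
        north = (pts["y"] > 50).mean()
        assert north == pytest.approx(0.9, abs=0.05)

    def test_draws_are_distinct_cells(self):
        grid = ek.GridSpec(20, 20, 1.0)
        pts = sample_presences(np.ones(grid.shape), grid, 400, seed=1)
        assert len(pts.drop_duplicates()) == 400
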