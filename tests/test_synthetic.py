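import numpy as np
import pytest

import esdm
from esdm.exceptions import EmptyDataError
from esdm.synthetic import Response, fixture_correlation

from conftest import stack_from_arrays


def _pairwise_r(stack, i, j):
    flat = [stack.layers[n].ravel() for n in stack.layer_names]
    return np.corrcoef(flat[i], flat[j])[0, 1]


class TestMakeStack:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_identity_target_gives_uncorrelated_layers(self, seed):
        stack = esdm.make_stack((100, 100), 3, seed=seed)
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(_pairwise_r(stack, i, j)) < 0.15

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_high_target_correlation_is_reached(self, seed):
        corr = np.eye(2)
        corr[0, 1] = corr[1, 0] = 0.95
        stack = esdm.make_stack((100, 100), 2, correlation=corr, seed=seed)
        assert _pairwise_r(stack, 0, 1) > 0.85

    def test_layers_standardized(self):
        stack = esdm.make_stack((50, 50), 4, seed=3)
        for grid in stack.layers.values():
            assert abs(grid.mean()) < 1e-10
            np.testing.assert_allclose(grid.std(), 1.0, atol=1e-10)

    def test_single_cell_grid_rejected(self):
        with pytest.raises(ValueError, match="insufficient cells"):
            esdm.make_stack((1, 1), 2, seed=0)

    def test_non_positive_definite_matrix_rejected(self):
        bad = np.array([[1.0, 0.99], [0.99, 1.0]])
        bad[0, 1] = bad[1, 0] = 1.2  # |r| > 1 cannot be a correlation
        with pytest.raises(ValueError):
            esdm.make_stack((20, 20), 2, correlation=bad, seed=0)

    def test_seed_determinism(self):
        a = esdm.make_stack((30, 30), 3, seed=7)
        b = esdm.make_stack((30, 30), 3, seed=7)
        for name in a.layer_names:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])


class TestResponses:
    def test_gaussian_peaks_at_one_at_its_optimum(self):
        r = Response("v", "gaussian", loc=2.0, scale=0.5)
        assert r(np.array([2.0]))[0] == 1.0

    def test_logistic_is_half_at_midpoint(self):
        r = Response("v", "logistic", loc=1.0, scale=0.3)
        assert r(np.array([1.0]))[0] == 0.5

    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            Response("v", "gaussian", scale=0.0)
        with pytest.raises(ValueError):
            Response("v", "logistic", scale=0.0)

    def test_product_rule_zero_is_absorbing(self):
        grad = np.linspace(-5, 5, 25).reshape(5, 5)
        stack = stack_from_arrays({"a": grad, "b": grad})
        vs = esdm.true_suitability(
            stack,
            [Response("a", "linear", loc=0.0, scale=0.0),  # identically 0
             Response("b", "gaussian", loc=0.0, scale=1.0)],
            rule="product",
        )
        np.testing.assert_array_equal(vs.true_suitability, 0.0)

    def test_suitability_bounded_and_nan_on_nodata(self):
        grad = np.linspace(-3, 3, 16).reshape(4, 4)
        grad[0, 0] = np.nan
        stack = stack_from_arrays({"a": grad})
        vs = esdm.true_suitability(stack, [Response("a", "logistic", 0.0, 0.5)])
        assert np.isnan(vs.true_suitability[0, 0])
        off = vs.true_suitability[~stack.nodata_mask]
        assert off.min() >= 0.0 and off.max() <= 1.0

    def test_gaussian_argmax_sits_at_value_nearest_optimum(self):
        # monotone gradient layer: the argmax cell holds the value nearest loc
        vals = np.linspace(-2.0, 2.0, 100).reshape(10, 10)
        stack = stack_from_arrays({"g": vals})
        vs = esdm.true_suitability(stack, [Response("g", "gaussian", loc=0.77, scale=0.4)])
        best = np.nanargmax(vs.true_suitability)
        nearest = np.argmin(np.abs(vals.ravel() - 0.77))
        assert best == nearest

    def test_missing_variable_rejected(self):
        stack = stack_from_arrays({"a": np.zeros((3, 3))})
        with pytest.raises(KeyError, match="zzz"):
            esdm.true_suitability(stack, [Response("zzz", "gaussian")])


class TestSamplePresences:
    def test_forced_support_selects_exactly_those_cells(self):
        suit = np.zeros((5, 5))
        suit[1, 2] = suit[3, 3] = suit[0, 0] = 1.0
        stack = stack_from_arrays({"a": np.zeros((5, 5))})
        vs = esdm.VirtualSpecies(
            responses=[], true_suitability=suit, combination_rule="product", stack=stack
        )
        occ = esdm.sample_presences(vs, 3, seed=0)
        rows, cols = stack.transform.xy_to_rowcol(
            occ.points["x"].to_numpy(), occ.points["y"].to_numpy()
        )
        assert sorted(zip(rows, cols)) == [(0, 0), (1, 2), (3, 3)]

    def test_seed_contract(self):
        _, vs, _ = esdm.default_fixture(seed=0, shape=(30, 30), n_presence=10)
        a = esdm.sample_presences(vs, 20, seed=5).points
        b = esdm.sample_presences(vs, 20, seed=5).points
        c = esdm.sample_presences(vs, 20, seed=6).points
        assert a.equals(b)
        assert not a.equals(c)

    def test_zero_presences_rejected(self):
        _, vs, _ = esdm.default_fixture(seed=0, shape=(20, 20), n_presence=5)
        with pytest.raises(EmptyDataError):
            esdm.sample_presences(vs, 0, seed=0)

    def test_oversampling_rejected(self):
        suit = np.zeros((4, 4))
        suit[0, 0] = 1.0
        stack = stack_from_arrays({"a": np.zeros((4, 4))})
        vs = esdm.VirtualSpecies([], suit, "product", stack)
        with pytest.raises(ValueError, match="exceeds"):
            esdm.sample_presences(vs, 2, seed=0)

    def test_sampling_frequency_tracks_suitability(self):
        # unbiasedness: selection frequency over 200 replicate draws correlates
        # with true suitability on a small grid
        rng = np.random.default_rng(42)
        suit = rng.uniform(0.05, 1.0, size=(5, 5))
        stack = stack_from_arrays({"a": np.zeros((5, 5))})
        vs = esdm.VirtualSpecies([], suit, "product", stack)
        counts = np.zeros(25)
        for rep in range(200):
            occ = esdm.sample_presences(vs, 5, seed=rep)
            r, c = stack.transform.xy_to_rowcol(
                occ.points["x"].to_numpy(), occ.points["y"].to_numpy()
            )
            np.add.at(counts, r * 5 + c, 1)
        assert np.corrcoef(counts, suit.ravel())[0, 1] > 0.9


class TestMakeFuture:
    def test_zero_shift_is_bit_exact_identity(self):
        stack, _, _ = esdm.default_fixture(seed=1, shape=(20, 20), n_presence=5)
        fut = esdm.make_future(stack, {})
        for name in stack.layer_names:
            np.testing.assert_array_equal(fut.layers[name], stack.layers[name])

    def test_additive_shift_is_exact(self):
        stack, _, _ = esdm.default_fixture(seed=1, shape=(20, 20), n_presence=5)
        fut = esdm.make_future(stack, {"env2": 2.0})
        valid = ~stack.nodata_mask
        np.testing.assert_array_equal(
            fut.layers["env2"][valid], stack.layers["env2"][valid] + 2.0
        )
        np.testing.assert_array_equal(fut.layers["env1"], stack.layers["env1"])
        np.testing.assert_array_equal(fut.nodata_mask, stack.nodata_mask)

    def test_unknown_layer_rejected(self):
        stack, _, _ = esdm.default_fixture(seed=1, shape=(10, 10), n_presence=5)
        with pytest.raises(KeyError, match="bogus"):
            esdm.make_future(stack, {"bogus": 1.0})

    def test_opposite_shift_restores_dyadic_data_bit_exactly(self):
        # with values and deltas on a dyadic grid the additive round trip is exact
        vals = (np.arange(16, dtype=float) / 8.0).reshape(4, 4)
        stack = stack_from_arrays({"a": vals})
        back = esdm.make_future(esdm.make_future(stack, {"a": 0.625}), {"a": -0.625})
        np.testing.assert_array_equal(back.layers["a"], vals)

    def test_opposite_shift_restores_general_data_to_machine_precision(self):
        stack, _, _ = esdm.default_fixture(seed=2, shape=(15, 15), n_presence=5)
        back = esdm.make_future(esdm.make_future(stack, {"env1": 1.3}), {"env1": -1.3})
        np.testing.assert_allclose(
            back.layers["env1"], stack.layers["env1"], rtol=0, atol=1e-15
        )


def test_fixture_decoys_track_causal_layers():
    stack, vs, occ = esdm.default_fixture(seed=4)
    flat = {n: stack.layers[n].ravel() for n in stack.layer_names}
    assert np.corrcoef(flat["env1"], flat["env3"])[0, 1] > 0.85
    assert np.corrcoef(flat["env2"], flat["env4"])[0, 1] > 0.85
    assert abs(np.corrcoef(flat["env1"], flat["env5"])[0, 1]) < 0.15
    assert occ.n_presence == 150
    assert fixture_correlation()[0, 2] == 0.9
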