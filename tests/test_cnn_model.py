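import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from sepredict import cnn_model as cm
from sepredict.cnn_model import (ALPHA_GRID, EPOCH_GRID, LAYER_GRID, LayerSpec,
                                 ModelSpec, TrainConfig, build_architecture,
                                 cross_entropy_loss, cross_validate,
                                 flatten_size, grid_search, predict_label,
                                 predict_proba, propagate_shapes, relu,
                                 softmax, stratified_folds, train)


class TestArchitecture:
    def test_two_layer_sequence(self):
        spec = build_architecture(2)
        kinds = [l.kind for l in spec.layers]
        assert kinds == ["conv", "pool", "conv", "pool", "dense", "softmax"]
        assert [l.kernels for l in spec.layers if l.kind == "conv"] == [32, 64]
        assert [l.pool_width for l in spec.layers if l.kind == "pool"] == [3, 3]

    def test_three_layer_adds_conv128_pool2(self):
        spec = build_architecture(3)
        assert [l.kernels for l in spec.layers if l.kind == "conv"] == [32, 64, 128]
        assert [l.pool_width for l in spec.layers if l.kind == "pool"] == [3, 3, 2]

    def test_four_layer_adds_conv256_pool2(self):
        spec = build_architecture(4)
        assert [l.kernels for l in spec.layers if l.kind == "conv"] == [32, 64, 128, 256]
        assert [l.pool_width for l in spec.layers if l.kind == "pool"] == [3, 3, 2, 2]

    def test_dense_and_softmax_sizes(self):
        for L in (2, 3, 4):
            spec = build_architecture(L)
            assert spec.layers[-2].units == 64
            assert spec.layers[-1].units == 2

    def test_invalid_layer_count(self):
        with pytest.raises(ValueError):
            build_architecture(5)

    def test_conv_stride_padding_locked(self):
        with pytest.raises(ValueError):
            LayerSpec(kind="conv", kernels=8, stride=2)


class TestShapePropagation:
    def test_two_layer_lengths(self):
        shapes = propagate_shapes(build_architecture(2))
        assert shapes == [("input", 1, 36), ("conv", 32, 36), ("pool", 32, 12),
                          ("conv", 64, 12), ("pool", 64, 4),
                          ("dense", 64, 1), ("softmax", 2, 1)]

    def test_three_layer_lengths(self):
        shapes = propagate_shapes(build_architecture(3))
        assert ("conv", 128, 4) in shapes and ("pool", 128, 2) in shapes
        assert flatten_size(build_architecture(3)) == 128 * 2

    def test_four_layer_lengths(self):
        shapes = propagate_shapes(build_architecture(4))
        assert ("conv", 256, 2) in shapes and ("pool", 256, 1) in shapes
        assert flatten_size(build_architecture(4)) == 256 * 1

    def test_all_models_flatten_to_256(self):
        assert {flatten_size(build_architecture(L)) for L in (2, 3, 4)} == {256}

    def test_too_short_input_is_error(self):
        spec = build_architecture(4, input_len=4)
        with pytest.raises(ValueError):
            propagate_shapes(spec)


class TestActivations:
    def test_relu_trivials(self):
        assert relu(-2) == 0
        assert relu(3) == 3

    @settings(max_examples=50, deadline=None)
    @given(hnp.arrays(np.float64, st.integers(1, 30),
                      elements=st.floats(-100, 100)))
    def test_relu_identity_property(self, x):
        np.testing.assert_allclose(relu(x) - relu(-x), x)

    def test_softmax_symmetry(self):
        np.testing.assert_allclose(softmax(np.array([0.0, 0.0])), [0.5, 0.5])

    def test_softmax_shift_invariance(self):
        for c in (-50.0, 0.0, 123.0):
            np.testing.assert_allclose(softmax(np.array([c, c, c])),
                                       [1 / 3] * 3)

    def test_softmax_closed_form(self):
        e = math.e
        np.testing.assert_allclose(softmax(np.array([1.0, 0.0])),
                                   [e / (1 + e), 1 / (1 + e)])
        np.testing.assert_allclose(softmax(np.array([1.0, 0.0])),
                                   [0.7311, 0.2689], atol=5e-5)

    def test_softmax_extreme_inputs_stable(self):
        out = softmax(np.array([1000.0, -1000.0]))
        assert np.isfinite(out).all()
        assert out.sum() == pytest.approx(1.0)


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        assert cross_entropy_loss(np.array([1.0, 0.0]), np.array([1, 0])) < 1e-10

    def test_half_gives_ln2(self):
        h = np.full(10, 0.5)
        y = np.array([1, 0] * 5)
        assert cross_entropy_loss(h, y) == pytest.approx(math.log(2))

    def test_scalar_loop_oracle_seed31(self):
        rng = np.random.default_rng(31)
        h = rng.random(7)
        y = rng.integers(0, 2, 7)
        expected = -sum(yi * math.log(hi) + (1 - yi) * math.log(1 - hi)
                        for hi, yi in zip(h, y)) / 7
        assert cross_entropy_loss(h, y) == pytest.approx(expected)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(8)
        h = rng.random(20)
        y = rng.integers(0, 2, 20)
        perm = rng.permutation(20)
        assert cross_entropy_loss(h, y) == pytest.approx(
            cross_entropy_loss(h[perm], y[perm]))

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.array([]), np.array([]))


def separable_set(seed=37, n=400):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(0, 0.2, size=(n, 36))
    X[:, 0] += np.where(y == 1, 2.0, -2.0)
    X[:, 1] += np.where(y == 1, 2.0, -2.0)
    return X, y


class TestTraining:
    def test_separable_set_reaches_full_accuracy(self):
        X, y = separable_set()
        spec = build_architecture(2)
        model = train(spec, X, y, TrainConfig(alpha=1e-3, epochs=100, seed=37,
                                              batch_size=64))
        assert (predict_label(model, X) == y).mean() >= 0.99

    def test_all_zero_labels_converge_to_negative(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100, 36))
        y = np.zeros(100, dtype=int)
        model = train(build_architecture(2), X, y,
                      TrainConfig(alpha=1e-3, epochs=30, seed=1, batch_size=32))
        assert (predict_label(model, X) == 0).all()

    def test_same_seed_identical_final_loss(self):
        X, y = separable_set(seed=5, n=200)
        spec = build_architecture(3)
        config = TrainConfig(alpha=5e-4, epochs=15, seed=11, batch_size=64)
        m1 = train(spec, X, y, config)
        m2 = train(spec, X, y, config)
        assert abs(m1.history["loss"][-1] - m2.history["loss"][-1]) < 1e-6
        for key in m1.params:
            np.testing.assert_array_equal(m1.params[key], m2.params[key])

    def test_history_length_and_finiteness(self):
        X, y = separable_set(seed=6, n=100)
        model = train(build_architecture(2), X, y,
                      TrainConfig(alpha=1e-3, epochs=12, seed=3, batch_size=32))
        assert len(model.history["loss"]) == 12
        assert len(model.history["accuracy"]) == 12
        assert all(np.isfinite(v) for v in model.history["loss"])

    def test_degenerate_mode_at_oversized_alpha(self):
        # 9:1 imbalance, weak signal, alpha=5e-2: collapses to all-negative,
        # accuracy = majority fraction (the large-alpha plateau)
        rng = np.random.default_rng(41)
        n = 1000
        y = np.concatenate([np.ones(100, int), np.zeros(900, int)])
        X = rng.normal(size=(n, 36))
        X[:100, 5] += 0.3
        perm = rng.permutation(n)
        X, y = X[perm], y[perm]
        model = train(build_architecture(2), X, y,
                      TrainConfig(alpha=5e-2, epochs=60, seed=41, batch_size=128))
        preds = predict_label(model, X)
        assert preds.sum() == 0
        assert abs((preds == y).mean() - 0.9) <= 0.01

    def test_wrong_feature_count_is_error(self):
        with pytest.raises(ValueError):
            train(build_architecture(2), np.zeros((10, 12)), np.zeros(10),
                  TrainConfig(epochs=1))

    def test_non_binary_labels_is_error(self):
        with pytest.raises(ValueError, match="binary"):
            train(build_architecture(2), np.zeros((4, 36)),
                  np.array([0, 1, 2, 1]), TrainConfig(epochs=1))


class TestPredict:
    def test_rows_sum_to_one(self):
        X, y = separable_set(seed=9, n=60)
        model = train(build_architecture(2), X, y,
                      TrainConfig(alpha=1e-3, epochs=5, seed=2, batch_size=32))
        probs = predict_proba(model, X)
        assert ((probs > 0) & (probs < 1)).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-6)

    def test_duplicated_rows_identical_outputs(self):
        X, y = separable_set(seed=10, n=40)
        model = train(build_architecture(2), X, y,
                      TrainConfig(alpha=1e-3, epochs=5, seed=2, batch_size=32))
        probs = predict_proba(model, np.vstack([X[:5], X[:5]]))
        # identical rows agree to float32 BLAS reduction-order noise (~1e-9)
        np.testing.assert_allclose(probs[:5], probs[5:], atol=1e-7)

    def test_hand_computed_forward_pass(self):
        # dense-softmax stub with hand-set parameters
        spec = ModelSpec(name="stub",
                         layers=(LayerSpec(kind="dense", units=2),
                                 LayerSpec(kind="softmax", units=2)),
                         input_len=3)
        params = {
            "dense_W": np.array([[1.0, 0.0], [0.0, 1.0], [1.0, -1.0]],
                                dtype=np.float32),
            "dense_b": np.array([0.0, 0.5], dtype=np.float32),
            "out_W": np.array([[2.0, 0.0], [0.0, 2.0]], dtype=np.float32),
            "out_b": np.array([0.0, 0.0], dtype=np.float32),
        }
        X = np.array([[1.0, 2.0, -1.0]])
        # dense pre-activation: (1*1 + 0 + -1*1, 0 + 2 + 1 + 0.5) = (0, 3.5)
        # relu -> (0, 3.5); logits = (0, 7); softmax closed form
        probs, _ = cm._forward(spec, params, X)
        expected = np.exp([0.0, 7.0]) / np.exp([0.0, 7.0]).sum()
        np.testing.assert_allclose(probs[0], expected, rtol=1e-6)

    def test_feature_count_mismatch_is_error(self):
        X, y = separable_set(seed=11, n=30)
        model = train(build_architecture(2), X, y,
                      TrainConfig(alpha=1e-3, epochs=2, seed=2, batch_size=16))
        with pytest.raises(ValueError):
            predict_proba(model, np.zeros((3, 20)))


class TestGradients:
    def test_numeric_gradient_check(self):
        """Backprop vs central finite differences on a tiny architecture."""
        rng = np.random.default_rng(123)
        spec = build_architecture(2, input_len=9)
        X = rng.normal(size=(6, 9)).astype(np.float32)
        y = np.array([0, 1, 1, 0, 1, 0])
        params = cm._init_params(spec, rng)
        params = {k: v.astype(np.float64) for k, v in params.items()}
        probs, cache = cm._forward(spec, params, X)
        grads = cm._backward(spec, params, cache, y)
        eps = 1e-5
        for key in ("conv0_W", "conv1_b", "dense_W", "out_W", "out_b"):
            flat_idx = 0  # check the first element of each tensor
            orig = params[key].flat[flat_idx]
            for sign, store in ((+1, "hi"), (-1, "lo")):
                params[key].flat[flat_idx] = orig + sign * eps
                p, _ = cm._forward(spec, params, X)
                loss = cross_entropy_loss(p[:, 1], y)
                if sign > 0:
                    hi = loss
                else:
                    lo = loss
            params[key].flat[flat_idx] = orig
            numeric = (hi - lo) / (2 * eps)
            assert grads[key].flat[flat_idx] == pytest.approx(numeric, abs=2e-4), key


class TestCrossValidation:
    def test_folds_partition_exactly(self):
        y = np.array([0, 1] * 5)
        folds = stratified_folds(y, 5, seed=0)
        test_sets = [set(te) for _, te in folds]
        assert all(len(te) == 2 for te in test_sets)
        assert set().union(*test_sets) == set(range(10))
        assert sum(len(te) for te in test_sets) == 10

    def test_stratification_preserves_class_balance(self):
        y = np.array([1] * 10 + [0] * 40)
        for _, te in stratified_folds(y, 5, seed=1):
            assert y[te].sum() == 2

    def test_leave_one_out_boundary(self):
        y = np.array([0, 1, 0, 1, 0, 1])
        folds = stratified_folds(y, 6, seed=0)
        assert len(folds) == 6
        assert all(len(te) == 1 for _, te in folds)

    def test_class_smaller_than_k_is_error(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="stratification"):
            stratified_folds(y, 4, seed=0)

    def test_null_model_matches_majority_seed41(self):
        rng = np.random.default_rng(41)
        n = 300
        y = np.concatenate([np.ones(30, int), np.zeros(270, int)])
        X = rng.normal(size=(n, 36))
        perm = rng.permutation(n)
        X, y = X[perm], y[perm]
        _, mean = cross_validate(build_architecture(2), X, y,
                                 TrainConfig(alpha=1e-4, epochs=10, seed=41,
                                             batch_size=64), k=5)
        assert mean["accuracy"] == pytest.approx(0.9, abs=0.05)

    def test_folds_never_leak_into_training(self):
        y = np.array([0, 1] * 10)
        for tr, te in stratified_folds(y, 5, seed=3):
            assert set(tr).isdisjoint(te)


class TestGridSearch:
    def test_grid_cardinality_is_264(self):
        assert len(LAYER_GRID) * len(EPOCH_GRID) * len(ALPHA_GRID) == 264
        assert list(EPOCH_GRID) == list(range(50, 151, 10))
        assert ALPHA_GRID == (1e-5, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2, 5e-2)

    def test_single_cell_grid(self):
        X, y = separable_set(seed=12, n=80)
        result = grid_search(X, y, seed=1, k=2, layer_grid=[2],
                             alpha_grid=[1e-3], epoch_grid=[5], batch_size=32)
        assert result.best == (2, 1e-3, 5)
        assert len(result.surface) == 1

    def test_surface_covers_full_grid(self):
        X, y = separable_set(seed=13, n=80)
        result = grid_search(X, y, seed=1, k=2, layer_grid=[2, 3],
                             alpha_grid=[1e-3, 1e-4], epoch_grid=[3, 6],
                             batch_size=32)
        assert len(result.surface) == 8
        assert set(result.surface["L"]) == {2, 3}

    def test_planted_optimum_recovered_seed43(self):
        # one alpha trains the separable set; the other is absurdly large
        X, y = separable_set(seed=43, n=200)
        result = grid_search(X, y, seed=43, k=2, layer_grid=[2],
                             alpha_grid=[1e-3, 5.0], epoch_grid=[30],
                             batch_size=64)
        assert result.best[1] == 1e-3
        assert result.best_accuracy > 0.95

    def test_empty_grid_is_error(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((10, 36)), np.zeros(10), layer_grid=[])

    def test_checkpointing_equals_fresh_run(self):
        # an e-epoch run is the deterministic prefix of a longer run
        X, y = separable_set(seed=14, n=100)
        spec = build_architecture(2)
        short = train(spec, X, y, TrainConfig(alpha=1e-3, epochs=4, seed=7,
                                              batch_size=32))
        snap = {}
        train(spec, X, y, TrainConfig(alpha=1e-3, epochs=8, seed=7, batch_size=32),
              checkpoints=[4], checkpoint_fn=lambda e, p: snap.update(
                  {k: v.copy() for k, v in p.items()}))
        for key in short.params:
            np.testing.assert_array_equal(short.params[key], snap[key])


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        X, y = separable_set(seed=15, n=50)
        model = train(build_architecture(2), X, y,
                      TrainConfig(alpha=1e-3, epochs=3, seed=4, batch_size=32))
        p = tmp_path / "model.json"
        cm.save_model(model, p)
        loaded = cm.load_model(p)
        np.testing.assert_allclose(predict_proba(loaded, X),
                                   predict_proba(model, X), rtol=1e-6)
        assert loaded.spec.name == model.spec.name
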