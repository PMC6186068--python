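"""Filter, dense stack, architecture schedule and training mechanics."""

import numpy as np
import pytest

from chromaforge import neural_models as nm
from chromaforge.window_dataset import DatasetSplit, WindowSample


def naive_stack_oracle(v, stack):
    """Direct per-neuron recursion: y_i = act(sum_k W_ik y_prev_k + b_i)."""
    y = np.asarray(v, dtype=float)
    for layer in stack.layers:
        z = np.empty(layer.W.shape[0])
        for i in range(layer.W.shape[0]):
            z[i] = sum(layer.W[i, k] * y[k] for k in range(len(y))) + layer.b[i]
        if layer.activation == "relu":
            y = np.maximum(z, 0.0)
        elif layer.activation == "sigmoid":
            y = 1.0 / (1.0 + np.exp(-z))
        else:
            y = z
    return y


def random_stack(rng, sizes, activations):
    layers = []
    for n_in, n_out, act in zip(sizes, sizes[1:], activations):
        layers.append(
            nm.DenseLayer(
                W=rng.normal(0, 0.5, (n_out, n_in)), b=rng.normal(0, 0.3, n_out),
                activation=act,
            )
        )
    return nm.DenseStackParams(layers)


class TestConvFilter:
    def test_zero_weights_give_half(self):
        params = nm.FilterParams(W0=np.zeros(3), beta0=0.0)
        sigma = nm.conv_filter_apply(np.random.default_rng(0).random((3, 7)), params)
        np.testing.assert_allclose(sigma, 0.5)

    def test_log3_weight_gives_three_quarters(self):
        params = nm.FilterParams(W0=np.array([np.log(3.0)]), beta0=0.0)
        sigma = nm.conv_filter_apply(np.ones((1, 4)), params)
        np.testing.assert_allclose(sigma, 0.75)

    def test_positional_independence(self, rng):
        params = nm.FilterParams(W0=rng.normal(size=4), beta0=0.3)
        x = rng.random((4, 10))
        perm = rng.permutation(10)
        np.testing.assert_allclose(
            nm.conv_filter_apply(x[:, perm], params),
            nm.conv_filter_apply(x, params)[perm],
        )

    def test_monotone_in_inputs_with_weight_sign(self, rng):
        params = nm.FilterParams(W0=np.array([2.0, -1.5]), beta0=0.0)
        x = rng.random((2, 5))
        up = x.copy()
        up[0] += 0.1
        down = x.copy()
        down[1] += 0.1
        assert (nm.conv_filter_apply(up, params) > nm.conv_filter_apply(x, params)).all()
        assert (nm.conv_filter_apply(down, params) < nm.conv_filter_apply(x, params)).all()

    def test_dimension_mismatch_rejected(self):
        params = nm.FilterParams(W0=np.zeros(3), beta0=0.0)
        with pytest.raises(ValueError):
            nm.conv_filter_apply(np.ones((4, 5)), params)


class TestLayerSizeSchedule:
    def test_forward_architecture(self):
        assert nm.layer_size_schedule(240, 3240, 4) == [460, 881, 1690, 3240]

    def test_backward_architecture(self):
        assert nm.layer_size_schedule(3240, 80, 3) == [943, 274, 80]

    def test_constant_when_in_equals_out(self):
        for n_layers in (1, 3, 6):
            assert nm.layer_size_schedule(10, 10, n_layers) == [10] * n_layers


class TestDenseStack:
    def test_identity_linear_layer(self):
        stack = nm.DenseStackParams(
            [nm.DenseLayer(W=np.eye(4), b=np.zeros(4), activation="linear")]
        )
        v = np.arange(4.0)
        np.testing.assert_array_equal(nm.dense_stack_apply(v, stack), v)

    def test_relu_clips_negative_preactivations(self):
        stack = nm.DenseStackParams(
            [nm.DenseLayer(W=np.eye(2), b=np.zeros(2), activation="relu")]
        )
        np.testing.assert_array_equal(
            nm.dense_stack_apply(np.array([-1.0, 2.0]), stack), [0.0, 2.0]
        )

    def test_hand_computed_two_layer_net(self):
        stack = nm.DenseStackParams(
            [
                nm.DenseLayer(W=np.array([[1.0], [-1.0]]), b=np.zeros(2), activation="relu"),
                nm.DenseLayer(W=np.array([[2.0, 5.0]]), b=np.zeros(1), activation="relu"),
            ]
        )
        np.testing.assert_array_equal(nm.dense_stack_apply(np.array([3.0]), stack), [6.0])

    @pytest.mark.parametrize("acts", [("relu", "relu", "linear"), ("relu", "sigmoid", "sigmoid")])
    def test_matches_naive_recursion_oracle(self, rng, acts):
        stack = random_stack(rng, [5, 7, 4, 3], acts)
        v = rng.normal(size=5)
        fast = nm.dense_stack_apply(v, stack)
        slow = naive_stack_oracle(v, stack)
        np.testing.assert_allclose(fast, slow, rtol=1e-10)

    def test_dropout_only_in_train_mode_and_rescales(self, rng):
        stack = random_stack(rng, [6, 50, 4], ("relu", "linear"))
        v = rng.random(6)
        a = nm.dense_stack_apply(v, stack)
        b = nm.dense_stack_apply(v, stack, train_mode=False, dropout_rate=0.5)
        np.testing.assert_array_equal(a, b)
        dropped = nm.dense_stack_apply(
            v, stack, train_mode=True, dropout_rate=0.5, rng=np.random.default_rng(0)
        )
        assert not np.allclose(a, dropped)

    def test_incompatible_layer_sizes_rejected(self):
        with pytest.raises(ValueError):
            nm.DenseStackParams(
                [
                    nm.DenseLayer(W=np.ones((3, 2)), b=np.zeros(3), activation="relu"),
                    nm.DenseLayer(W=np.ones((2, 4)), b=np.zeros(2), activation="relu"),
                ]
            )


class TestForwardBackwardPredict:
    def test_output_lengths_at_w80(self):
        model = nm.init_forward_model(n_factors=5, w=80, seed=0)
        out = model.predict(np.random.default_rng(0).random((5, 240)))
        assert out.shape == (3240,)
        stack = nm.init_backward_stack(w=80, seed=0)
        assert nm.backward_predict(np.zeros(3240), stack).shape == (80,)

    def test_zero_weight_stack_outputs(self):
        model = nm.init_forward_model(n_factors=3, w=4, seed=0)
        for layer in model.stack.layers:
            layer.W[:] = 0
        out = model.predict(np.zeros((3, 12)))
        np.testing.assert_array_equal(out, np.zeros(10))
        bstack = nm.init_backward_stack(w=4, seed=0)
        for layer in bstack.layers:
            layer.W[:] = 0
        np.testing.assert_allclose(nm.backward_predict(np.ones(10), bstack), 0.5)

    def test_inference_deterministic(self, rng):
        model = nm.init_forward_model(n_factors=4, w=6, seed=2)
        x = rng.random((4, 18))
        np.testing.assert_array_equal(model.predict(x), model.predict(x))

    def test_backward_outputs_strictly_in_unit_interval(self, rng):
        stack = nm.init_backward_stack(w=6, seed=3)
        out = nm.backward_predict(rng.random(21), stack)
        assert (out > 0).all() and (out < 1).all()


def tiny_split(rng, n=40, n_factors=3, w=4):
    samples = []
    for k in range(n):
        block = rng.random((n_factors, 3 * w))
        target = rng.random(w * (w + 1) // 2)
        samples.append(
            WindowSample(chrom="c", start_bin=k, orientation="forward",
                         input_block=block, target=target)
        )
    return DatasetSplit(train=samples[:30], validation=samples[30:], test=[],
                        split_seed=0, train_regions=[], test_regions=[])


class TestTraining:
    def test_training_cost_decreases(self, rng):
        split = tiny_split(rng)
        cfg = nm.TrainConfig(max_epochs=30, n_batches=3, dropout=0.0,
                             learning_rate=0.1, seed=0)
        _, hist = nm.train_forward(split, cfg)
        assert hist.train_cost[-1] < hist.train_cost[0]

    def test_bit_reproducible_given_seed(self, rng):
        split = tiny_split(rng)
        cfg = nm.TrainConfig(max_epochs=5, n_batches=3, seed=7)
        m1, _ = nm.train_forward(split, cfg)
        m2, _ = nm.train_forward(split, cfg)
        np.testing.assert_array_equal(m1.filter.W0, m2.filter.W0)
        for l1, l2 in zip(m1.stack.layers, m2.stack.layers):
            np.testing.assert_array_equal(l1.W, l2.W)

    def test_empty_sets_rejected(self, rng):
        split = tiny_split(rng)
        split.validation = []
        with pytest.raises(ValueError):
            nm.train_forward(split, nm.TrainConfig(max_epochs=1))

    def test_backward_zero_epochs_returns_initialization(self, rng):
        w = 4
        X = rng.random((20, w * (w + 1) // 2))
        Y = rng.random((20, w))
        init = nm.init_backward_stack(w, seed=5)
        ref = init.copy()
        cfg = nm.TrainConfig(max_epochs=0, seed=5)
        stack, hist = nm.train_backward(X[:15], Y[:15], X[15:], Y[15:], cfg, stack=init)
        for la, lb in zip(stack.layers, ref.layers):
            np.testing.assert_array_equal(la.W, lb.W)
            np.testing.assert_array_equal(la.b, lb.b)


class TestOrientation:
    def test_flip_preserves_model_outputs_exactly(self, rng):
        model = nm.init_forward_model(n_factors=4, w=5, seed=1)
        blocks = rng.random((6, 4, 15))
        # force an anti-correlated filter against track 0
        model.filter.W0[0] = -3.0
        before = np.stack([model.predict(b) for b in blocks])
        flipped_model, flipped = nm.orient_forward_model(model, blocks, reference_index=0)
        assert flipped
        after = np.stack([flipped_model.predict(b) for b in blocks])
        np.testing.assert_allclose(after, before, rtol=1e-12, atol=1e-12)
        sigma = flipped_model.states(blocks)
        ref = blocks[:, 0, :]
        assert np.corrcoef(sigma.ravel(), ref.ravel())[0, 1] > 0
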