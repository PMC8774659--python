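import numpy as np
import pytest

from ergcn.data_io import ValidationError
from ergcn.model import (
    ErgcnParameters,
    ModelConfig,
    cross_entropy,
    forward,
    gcn_layer,
    init_parameters,
    loss_and_grads,
    train,
)
from ergcn.network import normalize_adjacency
from conftest import random_adjacency


@pytest.fixture
def tiny_instance():
    """m=6, n=5, h=3, F=2 — small enough for finite-difference gradients."""
    rng = np.random.default_rng(1)
    X = rng.normal(size=(6, 5))
    S = normalize_adjacency(random_adjacency(rng, 6, 0.4)).matrix
    y = rng.integers(0, 2, size=6)
    mask = np.array([1, 1, 0, 1, 0, 1], bool)
    return X, S, y, mask


class TestInit:
    def test_deterministic(self):
        a = init_parameters(100, 64, 4, seed=3)
        b = init_parameters(100, 64, 4, seed=3)
        for k in a.blocks():
            np.testing.assert_array_equal(a.blocks()[k], b.blocks()[k])

    def test_shapes(self):
        p = init_parameters(100, 64, 4, seed=0)
        assert p.W1.shape == (100, 64)
        assert p.skip_weight.shape == (100, 64) and p.skip_bias.shape == (64,)
        assert p.W2.shape == (64, 4)
        np.testing.assert_array_equal(p.skip_bias, 0.0)

    def test_glorot_bound(self):
        p = init_parameters(100, 64, 4, seed=0)
        bound = np.sqrt(6.0 / (100 + 64))
        assert np.abs(p.W1).max() <= bound
        assert np.abs(p.W2).max() <= np.sqrt(6.0 / (64 + 4))


class TestGcnLayer:
    def test_identity_operator(self, rng):
        H = rng.normal(size=(4, 4))
        np.testing.assert_array_equal(gcn_layer(np.eye(4), H, np.eye(4)), H)

    def test_two_node_average(self):
        S = np.full((2, 2), 0.5)
        out = gcn_layer(S, np.array([[2.0], [0.0]]), np.array([[1.0]]))
        np.testing.assert_allclose(out, [[1.0], [1.0]], atol=1e-15)

    def test_matches_triple_product_oracle(self, rng):
        S = normalize_adjacency(random_adjacency(rng, 7)).matrix
        H, W = rng.normal(size=(7, 4)), rng.normal(size=(4, 3))
        expected = np.array(
            [[sum(S[i, k] * sum(H[k, d] * W[d, j] for d in range(4)) for k in range(7))
              for j in range(3)] for i in range(7)]
        )
        np.testing.assert_allclose(gcn_layer(S, H, W), expected, atol=1e-12)


class TestForward:
    def test_probability_rows_sum_to_one(self, tiny_instance):
        X, S, _, _ = tiny_instance
        params = init_parameters(5, 3, 2, seed=0)
        for variant in ("ergcn", "gcn", "mlp"):
            res = forward(X, S, params, ModelConfig(hidden_dim=3, variant=variant))
            np.testing.assert_allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-6)
            assert (res.probabilities >= 0).all() and (res.probabilities <= 1).all()
            np.testing.assert_array_equal(
                res.predicted_labels, res.probabilities.argmax(axis=1)
            )

    def test_zero_skip_equals_plain_gcn(self, tiny_instance):
        X, S, _, _ = tiny_instance
        params = init_parameters(5, 3, 2, seed=0)
        params.skip_weight[:] = 0.0
        params.skip_bias[:] = 0.0
        r1 = forward(X, S, params, ModelConfig(hidden_dim=3, variant="ergcn"))
        r2 = forward(X, S, params, ModelConfig(hidden_dim=3, variant="gcn"))
        np.testing.assert_array_equal(r1.probabilities, r2.probabilities)

    def test_inference_is_deterministic(self, tiny_instance):
        X, S, _, _ = tiny_instance
        params = init_parameters(5, 3, 2, seed=0)
        cfg = ModelConfig(hidden_dim=3, dropout_rate=0.5)
        a = forward(X, S, params, cfg, training=False)
        b = forward(X, S, params, cfg, training=False)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)

    def test_mlp_ignores_graph(self, tiny_instance):
        X, S, _, _ = tiny_instance
        params = init_parameters(5, 3, 2, seed=0)
        cfg = ModelConfig(hidden_dim=3, variant="mlp")
        a = forward(X, S, params, cfg)
        b = forward(X, np.eye(6), params, cfg)
        c = forward(X, None, params, cfg)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)
        np.testing.assert_array_equal(a.probabilities, c.probabilities)

    def test_embeddings_are_pre_dropout_hp(self, tiny_instance):
        X, S, _, _ = tiny_instance
        params = init_parameters(5, 3, 2, seed=0)
        res = forward(X, S, params, ModelConfig(hidden_dim=3))
        H1 = np.maximum(S @ X @ params.W1, 0)
        Hp = H1 + np.maximum(X @ params.skip_weight + params.skip_bias, 0)
        np.testing.assert_allclose(res.embeddings, Hp, atol=1e-12)


class TestCrossEntropy:
    def test_perfect_one_hot_is_zero(self):
        P = np.eye(3)
        assert cross_entropy(P, np.arange(3), np.ones(3, bool)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_closed_form(self):
        P = np.full((5, 4), 0.25)
        mask = np.array([1, 0, 1, 0, 1], bool)
        assert cross_entropy(P, np.zeros(5, int), mask) == pytest.approx(3 * np.log(4), abs=1e-12)

    def test_unmasked_rows_ignored(self, rng):
        P = rng.dirichlet(np.ones(3), size=6)
        y = rng.integers(0, 3, 6)
        mask = np.array([1, 1, 1, 0, 0, 0], bool)
        base = cross_entropy(P, y, mask)
        P2 = P.copy()
        P2[3:] = rng.dirichlet(np.ones(3), size=3)
        assert cross_entropy(P2, y, mask) == base

    def test_empty_mask_raises(self):
        with pytest.raises(ValidationError):
            cross_entropy(np.full((2, 2), 0.5), np.zeros(2, int), np.zeros(2, bool))

    def test_loss_non_negative(self, rng):
        P = rng.dirichlet(np.ones(4), size=10)
        assert cross_entropy(P, rng.integers(0, 4, 10), np.ones(10, bool)) >= 0


class TestGradients:
    @pytest.mark.parametrize("variant", ["ergcn", "gcn", "mlp"])
    def test_finite_difference_check(self, tiny_instance, variant):
        """Analytic gradients match central differences to 1e-4 relative."""
        X, S, y, mask = tiny_instance
        params = init_parameters(5, 3, 2, seed=0)
        _, grads = loss_and_grads(X, S, params, y, mask, variant)
        eps = 1e-6
        for name, W in params.blocks().items():
            numeric = np.zeros_like(W)
            it = np.nditer(W, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                W[idx] += eps
                lp, _ = loss_and_grads(X, S, params, y, mask, variant)
                W[idx] -= 2 * eps
                lm, _ = loss_and_grads(X, S, params, y, mask, variant)
                W[idx] += eps
                numeric[idx] = (lp - lm) / (2 * eps)
            scale = max(np.abs(numeric).max(), 1e-8)
            assert np.abs(numeric - grads[name]).max() / scale < 1e-4, name

    def test_gradient_respects_mask(self, tiny_instance):
        """Gradients are unchanged by the labels of unmasked nodes."""
        X, S, y, mask = tiny_instance
        params = init_parameters(5, 3, 2, seed=0)
        _, g1 = loss_and_grads(X, S, params, y, mask, "ergcn")
        y2 = y.copy()
        y2[~mask] = 1 - y2[~mask]
        _, g2 = loss_and_grads(X, S, params, y2, mask, "ergcn")
        for k in g1:
            np.testing.assert_array_equal(g1[k], g2[k])


class TestTrain:
    def test_loss_decreases_on_separable_data(self, benchmark):
        from ergcn import build_network
        from conftest import BENCHMARK_THETA

        _, S = build_network(benchmark.expr, BENCHMARK_THETA)
        y = benchmark.labels.labels
        mask = np.ones(len(y), bool)
        mask[::5] = False
        cfg = ModelConfig(epochs=100, seed=0)
        _, hist = train(benchmark.expr.values, S, y, mask, cfg)
        assert np.isfinite(hist).all()
        assert hist[-1] < hist[0]

    def test_same_seed_identical_history(self, tiny_instance):
        X, S, y, mask = tiny_instance
        cfg = ModelConfig(hidden_dim=3, epochs=30, seed=5)
        _, h1 = train(X, S, y, mask, cfg)
        _, h2 = train(X, S, y, mask, cfg)
        np.testing.assert_allclose(h1, h2, atol=1e-10)

    def test_heldout_accuracy_on_benchmark(self, benchmark):
        from ergcn import build_network
        from conftest import BENCHMARK_THETA

        _, S = build_network(benchmark.expr, BENCHMARK_THETA)
        y = benchmark.labels.labels
        mask = np.ones(len(y), bool)
        mask[::5] = False  # hold out 20%, stratified by construction order
        cfg = ModelConfig(seed=0)
        params, _ = train(benchmark.expr.values, S, y, mask, cfg)
        res = forward(benchmark.expr.values, S, params, cfg)
        acc = (res.predicted_labels[~mask] == y[~mask]).mean()
        assert acc >= 0.95

    def test_missing_class_warns(self, tiny_instance):
        X, S, y, _ = tiny_instance
        y = np.array([0, 0, 0, 1, 1, 1])
        mask = np.array([1, 1, 1, 0, 0, 0], bool)  # class 1 absent from training
        with pytest.warns(UserWarning, match="lacks samples"):
            train(X, S, y, mask, ModelConfig(hidden_dim=3, epochs=2), n_classes=2)
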