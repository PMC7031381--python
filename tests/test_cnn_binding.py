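import numpy as np
import pytest

from neopred import cnn_binding as cb
from neopred.errors import ConfigError, DegenerateLabels, ShapeError


def small_config(**overrides):
    defaults = dict(n_kernels1=3, n_kernels2=2, kernel_window=3, n_hidden=4,
                    batch_size=8, epochs=2, seed=0, learning_rate=0.05,
                    momentum=0.5, l2_weight=0.01, l1_activation=0.01)
    defaults.update(overrides)
    return cb.ModelConfig(**defaults)


def random_instance(seed=0, n=6, P=9, N=12):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(n, P, N))
    y = rng.integers(0, 2, size=n).astype(float)
    if y.min() == y.max():
        y[0] = 1 - y[0]
    return X, y


class TestLabelFromAffinity:
    def test_499_is_binder(self):
        assert cb.label_from_affinity(499.0) == 1

    def test_500_is_nonbinder(self):
        assert cb.label_from_affinity(500.0) == 0

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            cb.label_from_affinity(-1.0)

    def test_zero_raises(self):
        with pytest.raises(ValueError):
            cb.label_from_affinity(0.0)


class TestConvForward:
    def test_zero_input_zero_output(self):
        kernels = np.random.default_rng(0).normal(size=(4, 5, 183))
        out = cb.conv_forward(np.zeros((9, 183)), kernels)
        assert out.shape == (5, 4)
        assert np.all(out == 0.0)

    def test_all_ones_kernel_sums(self):
        out = cb.conv_forward(np.ones((9, 183)), np.ones((1, 5, 183)))
        assert out.shape == (5, 1)
        np.testing.assert_allclose(out, 915.0)

    def test_kernel_larger_than_input(self):
        with pytest.raises(ShapeError):
            cb.conv_forward(np.ones((4, 183)), np.ones((1, 5, 183)))

    def test_stride_fixed(self):
        with pytest.raises(ConfigError):
            cb.conv_forward(np.ones((9, 183)), np.ones((1, 5, 183)), stride=2)

    @pytest.mark.parametrize("seed", range(5))
    def test_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        P, N, K, M = 9, 14, 3, 4
        X = rng.normal(size=(P, N))
        W = rng.normal(size=(K, M, N))
        b = rng.normal(size=K)
        out = cb.conv_forward(X, W, bias=b)
        expected = np.zeros((P - M + 1, K))
        for i in range(P - M + 1):
            for k in range(K):
                acc = b[k]
                for m in range(M):
                    for n in range(N):
                        acc += W[k, m, n] * X[i + m, n]
                expected[i, k] = max(acc, 0.0)
        np.testing.assert_allclose(out, expected, rtol=1e-12)


class TestModelForward:
    def test_zero_weights_give_half(self):
        config = small_config()
        model = cb.init_model(config, (9, 12))
        for k in model.weights:
            model.weights[k] = np.zeros_like(model.weights[k])
        trace = cb.model_forward(model, np.random.default_rng(0).normal(size=(9, 12)))
        assert trace.probability == pytest.approx(0.5)

    def test_probability_strictly_inside_unit_interval(self):
        model = cb.init_model(small_config(seed=4), (9, 12))
        X, _ = random_instance(seed=4)
        trace = cb.model_forward(model, X)
        assert np.all(trace.probability > 0) and np.all(trace.probability < 1)

    def test_composes_layer_oracles(self):
        config = small_config(seed=5)
        model = cb.init_model(config, (9, 12))
        X, _ = random_instance(seed=5, n=3)
        trace = cb.model_forward(model, X)
        w = model.weights
        for s in range(3):
            a1 = cb.conv_forward(X[s], w["W1"], bias=w["b1"])
            a2 = cb.conv_forward(a1, w["W2"], bias=w["b2"])
            h = np.maximum(a2.ravel() @ w["W3"].T + w["b3"], 0.0)
            z = h @ w["w4"] + w["b4"]
            p = 1.0 / (1.0 + np.exp(-z))
            np.testing.assert_allclose(trace.conv1[s], a1, rtol=1e-12)
            np.testing.assert_allclose(trace.conv2[s], a2, rtol=1e-12)
            np.testing.assert_allclose(trace.hidden[s], h, rtol=1e-12)
            np.testing.assert_allclose(trace.probability[s], p, rtol=1e-12)

    def test_shape_mismatch(self):
        model = cb.init_model(small_config(), (9, 12))
        with pytest.raises(ShapeError):
            cb.model_forward(model, np.ones((9, 5)))

    def test_activations_nonnegative(self):
        model = cb.init_model(small_config(seed=6), (9, 12))
        X, _ = random_instance(seed=6)
        trace = cb.model_forward(model, X)
        assert np.all(trace.conv1 >= 0)
        assert np.all(trace.conv2 >= 0)
        assert np.all(trace.hidden >= 0)


class TestObjective:
    def test_perfect_predictions_no_reg_zero_loss(self):
        # drive probabilities to the labels via huge output weights
        config = small_config(l2_weight=0.0, l1_activation=0.0)
        model = cb.init_model(config, (9, 12))
        X = np.ones((2, 9, 12)) * 5
        # labels equal to predictions: use the model's own outputs as labels
        p = cb.model_forward(model, X).probability
        y = (p >= 0.5).astype(float)
        # loss of a perfect predictor is 0; here check consistency instead:
        loss, _ = cb.objective(model, X, y, l2_weight=0.0, l1_activation=0.0)
        expected = -np.sum(np.log(y * p + (1 - y) * (1 - p)))
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_single_sample_half_probability(self):
        config = small_config(l2_weight=0.0, l1_activation=0.0)
        model = cb.init_model(config, (9, 12))
        for k in model.weights:
            model.weights[k] = np.zeros_like(model.weights[k])
        X = np.ones((1, 9, 12))
        loss, _ = cb.objective(model, X, np.array([1.0]),
                               l2_weight=0.0, l1_activation=0.0)
        assert loss == pytest.approx(np.log(2), rel=1e-12)

    def test_violations_reported(self):
        config = small_config(max_norm=1e-6)
        model = cb.init_model(config, (9, 12))
        X, y = random_instance()
        _, violations = cb.objective(model, X, y)
        assert violations  # random init exceeds a tiny bound

    @pytest.mark.parametrize("seed", range(3))
    def test_gradient_matches_finite_differences(self, seed):
        config = small_config(seed=seed)
        model = cb.init_model(config, (9, 12))
        X, y = random_instance(seed=seed)
        lam1, lam2 = 0.01, 0.01
        _, grads = cb._objective_and_grads(model, X, y, lam1, lam2)
        h = 1e-6
        rng = np.random.default_rng(seed + 100)
        for key, W in model.weights.items():
            flat = W.reshape(-1)
            g = grads[key].reshape(-1)
            idxs = rng.choice(flat.size, size=min(15, flat.size), replace=False)
            for idx in idxs:
                orig = flat[idx]
                flat[idx] = orig + h
                lp, _ = cb._objective_and_grads(model, X, y, lam1, lam2)
                flat[idx] = orig - h
                lm, _ = cb._objective_and_grads(model, X, y, lam1, lam2)
                flat[idx] = orig
                fd = (lp - lm) / (2 * h)
                denom = max(abs(fd), abs(g[idx]), 1e-8)
                assert abs(fd - g[idx]) / denom < 1e-5, (key, idx)


class TestTrain:
    def make_separable(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 9, 12))
        y = (X[:, 0, 0] > 0).astype(float)
        X[y == 1, 0, 0] += 2.0
        return cb.TrainingSet(X=X, y=y)

    def test_deterministic_under_seed(self):
        data = self.make_separable()
        config = small_config(epochs=3)
        m1 = cb.train(config, data)
        m2 = cb.train(config, data)
        for k in m1.weights:
            np.testing.assert_array_equal(m1.weights[k], m2.weights[k])

    def test_max_norm_projection_postcondition(self):
        data = self.make_separable()
        config = small_config(epochs=3, max_norm=1.0)
        model = cb.train(config, data)
        for _, norm in cb._neuron_norms(model.weights):
            assert norm <= 1.0 + 1e-12

    def test_max_norm_holds_after_every_update(self):
        data = self.make_separable()
        config = small_config(epochs=2, max_norm=0.5)
        seen = []

        def check(model, epoch, loss):
            seen.append(max(n for _, n in cb._neuron_norms(model.weights)))

        cb.train(config, data, callback=check)
        assert seen and max(seen) <= 0.5 + 1e-12

    def test_loss_decreases_on_separable_data(self):
        data = self.make_separable(n=200, seed=1)
        model0 = cb.train(small_config(epochs=0), data)  # initialization only
        loss0, _ = cb.objective(model0, data.X, data.y)
        config = small_config(epochs=10, learning_rate=0.01)
        model = cb.train(config, data)
        loss1, _ = cb.objective(model, data.X, data.y)
        assert loss1 < loss0

    def test_single_class_raises(self):
        data = self.make_separable()
        data.y[:] = 1.0
        with pytest.raises(DegenerateLabels):
            cb.train(small_config(), data)


class TestGridSearch:
    def test_enumerates_product(self, monkeypatch):
        data = TestTrain().make_separable(n=40)
        val = TestTrain().make_separable(n=20, seed=9)
        calls = []
        real_train = cb.train

        def counting_train(config, d, callback=None):
            calls.append(config)
            return real_train(config, d, callback)

        monkeypatch.setattr(cb, "train", counting_train)
        grids = {
            "learning_rate": [0.001, 0.01, 0.1],
            "l2_weight": [0.0001, 0.001, 0.01],
            "l1_activation": [0.0001, 0.001, 0.01],
            "momentum": [0.1, 0.5, 0.9],
        }
        base = small_config(epochs=1)
        cb.grid_search(base, grids, data, val)
        assert len(calls) == 81

    def test_best_and_tie_break(self, monkeypatch):
        data = TestTrain().make_separable(n=30)
        val = TestTrain().make_separable(n=20, seed=9)
        # force identical AUCs: stub predict_proba to constant ordering
        aucs = iter([0.7, 0.9, 0.9])
        monkeypatch.setattr(cb, "train", lambda c, d, callback=None: cb.init_model(c, d.X.shape[1:]))
        monkeypatch.setattr(cb, "roc_auc", lambda s, l: next(aucs))
        best = cb.grid_search(small_config(epochs=1),
                              {"learning_rate": [0.001, 0.01, 0.1]}, data, val)
        assert best.learning_rate == 0.01  # first of the two tied maxima

    def test_empty_validation(self):
        data = TestTrain().make_separable()
        empty = cb.TrainingSet(X=np.empty((0, 9, 12)), y=np.empty(0))
        with pytest.raises(ConfigError):
            cb.grid_search(small_config(), {"learning_rate": [0.01]}, data, empty)


class TestEvaluate:
    def test_perfect_separation(self):
        report = cb.evaluate([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert report.auc == 1.0

    def test_f1_closed_form(self):
        # TP=2, FP=1, FN=1 at threshold 0.5
        scores = [0.9, 0.8, 0.7, 0.1]
        labels = [1, 1, 0, 1]
        report = cb.evaluate(scores, labels)
        assert report.f1 == pytest.approx(2 * 2 / (2 * 2 + 1 + 1))

    @pytest.mark.parametrize("seed", range(5))
    def test_auc_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=10)
        labels = rng.integers(0, 2, size=10)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        total = 0.0
        for p in pos:
            for q in neg:
                total += 1.0 if p > q else (0.5 if p == q else 0.0)
        expected = total / (len(pos) * len(neg))
        assert cb.roc_auc(scores, labels) == pytest.approx(expected, rel=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabels):
            cb.evaluate([0.1, 0.9], [1, 1])


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path):
        model = cb.train(small_config(epochs=2), TestTrain().make_separable())
        path = str(tmp_path / "model.json")
        cb.save_model(model, path)
        loaded = cb.load_model(path)
        assert loaded.key == model.key
        assert loaded.config == model.config
        for k in model.weights:
            np.testing.assert_array_equal(loaded.weights[k], model.weights[k])
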