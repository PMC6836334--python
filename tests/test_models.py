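"""Architecture, gradients and training behaviour of the two regressors."""

import numpy as np
import pytest

from ncrus.errors import ConfigurationError, ModelStateError
from ncrus.models import (
    CnnConfig,
    RfConfig,
    build_cnn,
    train_rf,
)

TINY = CnnConfig(
    conv_kernel_counts=(3, 4, 5),
    conv_kernel_sizes=(3, 3, 3),
    fc_sizes=(6, 4, 1),
    input_length=16,
    input_channels=2,
    dropout_prob=0.0,
    grad_clip_norm=0.0,
    epochs=30,
    minibatch=8,
    initial_lr=0.01,
    seed=3,
)


class TestCnnArchitecture:
    def test_eighteen_layer_enumeration(self):
        model = build_cnn()
        kinds = [k for k, _ in model.architecture()]
        assert kinds == [
            "input",
            "conv", "batchnorm", "relu",
            "conv", "batchnorm", "relu", "maxpool",
            "conv", "batchnorm", "relu", "maxpool",
            "fc", "dropout", "fc", "dropout", "fc",
            "regression",
        ]
        assert len(kinds) == 18
        details = [d for k, d in model.architecture() if k == "conv"]
        assert details == [
            "17 kernels of size 11", "55 kernels of size 7", "70 kernels of size 11",
        ]
        fc = [d for k, d in model.architecture() if k == "fc"]
        assert fc == ["25 units", "25 units", "1 units"]

    def test_parameter_count_matches_layer_arithmetic(self):
        # conv: Cin*K*Cout + Cout; BN: 2*C; FC: D*M + M; flatten 150*70 = 10500
        expected = (
            (2 * 11 * 17 + 17) + 2 * 17
            + (17 * 7 * 55 + 55) + 2 * 55
            + (55 * 11 * 70 + 70) + 2 * 70
            + (10500 * 25 + 25) + (25 * 25 + 25) + (25 * 1 + 1)
        )
        assert expected == 312896  # frozen once from the arithmetic above
        assert build_cnn().parameter_count() == expected

    def test_forward_pass_finite_scalar_per_sample(self):
        model = build_cnn()
        out = model.forward(np.zeros((2, 601, 2), dtype=np.float32))
        assert out.shape == (2,) and np.all(np.isfinite(out))

    def test_wrong_input_shape_rejected(self):
        model = build_cnn()
        with pytest.raises(ConfigurationError):
            model.forward(np.zeros((2, 600, 2)))

    def test_lr_schedule_drops_at_quarter_points(self):
        assert CnnConfig(epochs=350).lr_drop_epochs() == (88, 175, 263)
        assert CnnConfig(epochs=50).lr_drop_epochs() == (13, 25, 38)


class TestCnnTraining:
    def test_gradients_match_finite_differences(self):
        model = build_cnn(TINY, dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 16, 2))
        y = rng.normal(size=5)

        def loss():
            return np.mean((model._forward(x, True)[:, 0] - y) ** 2)

        pred = model._forward(x, True)[:, 0]
        model._backward((2 * (pred - y) / 5)[:, None])
        for layer in model.layers:
            for p, g in layer.params_and_grads():
                for flat in rng.choice(p.size, size=min(6, p.size), replace=False):
                    idx = np.unravel_index(flat, p.shape)
                    eps, old = 1e-6, p[idx]
                    p[idx] = old + eps
                    up = loss()
                    p[idx] = old - eps
                    down = loss()
                    p[idx] = old
                    numeric = (up - down) / (2 * eps)
                    # relative where the gradient is O(1), absolute near zero
                    assert abs(numeric - g[idx]) <= 1e-5 * max(1.0, abs(numeric))

    def test_training_reduces_loss_on_toy_problem(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(20, 16, 2)).astype(np.float32)
        y = x[:, :, 0].mean(axis=1) * 0.3 + 0.7
        model = build_cnn(TINY)
        trace = model.fit(x, y)
        assert trace[-1] < trace[0]

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 16, 2)).astype(np.float32)
        y = rng.uniform(0.5, 1, 12).astype(np.float32)
        cfg = TINY
        a, b = build_cnn(cfg), build_cnn(cfg)
        a.fit(x, y)
        b.fit(x, y)
        for la, lb in zip(a.layers, b.layers):
            for (pa, _), (pb, _) in zip(la.params_and_grads(), lb.params_and_grads()):
                np.testing.assert_array_equal(pa, pb)
        np.testing.assert_array_equal(a.predict(x), b.predict(x))

    def test_inference_is_deterministic_despite_dropout(self):
        cfg = CnnConfig(**{**TINY.__dict__, "dropout_prob": 0.3})
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 16, 2)).astype(np.float32)
        y = rng.uniform(size=10).astype(np.float32)
        model = build_cnn(cfg)
        model.fit(x, y)
        np.testing.assert_array_equal(model.predict(x), model.predict(x))

    def test_untrained_predict_rejected(self):
        with pytest.raises(ModelStateError):
            build_cnn(TINY).predict(np.zeros((1, 16, 2)))

    def test_beats_constant_predictor_on_pseudo_validation(self, small_samples):
        # one leaf-out round on the small dataset with a short schedule
        from ncrus.dataset import balance_training_set

        x, meta = small_samples
        y = meta["rwc"].to_numpy()
        test_leaf = meta["leaf_id"].iloc[0]
        train_idx = np.flatnonzero((meta["leaf_id"] != test_leaf).to_numpy())
        bal = balance_training_set([(int(i), float(y[i])) for i in train_idx], 6, seed=3)
        kept = np.asarray(bal.kept_sample_ids, dtype=int)
        pseudo = np.asarray(bal.pseudo_validation_ids, dtype=int)
        cfg = CnnConfig(epochs=50, seed=5)
        model = build_cnn(cfg)
        model.fit(x[kept], y[kept])
        pred = model.predict(x[pseudo])
        rmse = np.sqrt(np.mean((pred - y[pseudo]) ** 2))
        rmse_const = np.sqrt(np.mean((y[kept].mean() - y[pseudo]) ** 2))
        assert rmse < rmse_const


class TestRandomForest:
    def test_monotone_single_feature_toy(self):
        rng = np.random.default_rng(0)
        f1 = rng.uniform(0, 1, 300)
        x = np.column_stack([f1, rng.normal(size=300), rng.normal(size=300),
                             rng.normal(size=300)])
        y = 0.5 + 0.5 * f1
        model = train_rf(x, y, RfConfig(seed=1))
        pred = model.predict(x)
        r = np.corrcoef(pred, y)[0, 1]
        assert r > 0.99

    def test_permuted_targets_destroy_signal(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(200, 4))
        y = x @ np.array([1.0, 0.5, 0.2, 0.1])
        hits = 0
        for rep in range(5):
            y_perm = rng.permutation(y)
            model = train_rf(x[:150], y_perm[:150], RfConfig(n_trees=100, seed=rep))
            r = np.corrcoef(model.predict(x[150:]), y_perm[150:])[0, 1]
            hits += abs(r) < 0.2
        assert hits >= 4  # null-data sanity holds in nearly all repeats

    def test_seeded_determinism(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(size=(100, 4))
        y = x[:, 0] + 0.1 * rng.normal(size=100)
        a = train_rf(x, y, RfConfig(seed=11)).predict(x)
        b = train_rf(x, y, RfConfig(seed=11)).predict(x)
        np.testing.assert_array_equal(a, b)

    def test_split_candidate_restriction(self):
        # resolved max_features is 2 (half of the 4 parameters); with random
        # subsets, even a dominated feature must appear in some splits
        rng = np.random.default_rng(9)
        x = rng.uniform(size=(400, 4))
        y = 2 * x[:, 0] + 0.01 * x[:, 1]
        model = train_rf(x, y, RfConfig(seed=2))
        assert model.forest.max_features == 2
        used = set()
        for tree in model.forest.estimators_[:50]:
            used.update(f for f in tree.tree_.feature if f >= 0)
        assert used - {0}  # restricted candidate subsets forced other features in

    def test_non_finite_features_rejected(self):
        x = np.array([[1.0, np.nan, 0.0, 0.0]] * 10)
        with pytest.raises(ConfigurationError):
            train_rf(x, np.ones(10))

    def test_constant_target_warns(self):
        rng = np.random.default_rng(1)
        with pytest.warns(UserWarning):
            train_rf(rng.uniform(size=(20, 4)), np.full(20, 0.9))
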