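import numpy as np
import pandas as pd
import pytest

from fscchange.exceptions import ConfigError, FormatError
from fscchange.geo_io import CLASS_ORDER
from fscchange.models import (
    MLP,
    BPNNSpec,
    PSOConfig,
    TrainedClassifier,
    load_model,
    predict,
    pso_minimize,
    save_model,
    train_baseline,
    train_bpnn,
    train_pso_bpnn,
)


def _gaussian_2class(n=200, gap=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(0, 1, size=(n // 2, 3)),
        rng.normal(gap, 1, size=(n // 2, 3)),
    ])
    y = ["Arbor"] * (n // 2) + ["Shrub"] * (n // 2)
    return X, y


class TestBaselines:
    @pytest.mark.parametrize("kind", ["RF", "SVM"])
    def test_separated_gaussians_learned(self, kind):
        for seed in range(5):
            X, y = _gaussian_2class(seed=seed)
            model = train_baseline(kind, X, y, seed=seed)
            pred, _ = predict(model, X)
            assert np.mean(np.array(pred) == np.array(y)) >= 0.95

    def test_duplicated_columns_tolerated(self):
        X, y = _gaussian_2class()
        X = np.hstack([X, X])
        model = train_baseline("RF", X, y)
        assert model.model.n_features_in_ == 6

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(1000, 3))
        y = np.array(["Arbor", "Shrub"] * 500)
        rng.shuffle(y)
        model = train_baseline("RF", X[:800], list(y[:800]))
        pred, _ = predict(model, X[800:])
        acc = np.mean(np.array(pred) == y[800:])
        assert abs(acc - 0.5) <= 0.1

    def test_single_class_rejected(self):
        with pytest.raises(ConfigError):
            train_baseline("RF", np.zeros((10, 2)), ["Arbor"] * 10)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigError):
            train_baseline("GBM", *_gaussian_2class())


class TestBPNN:
    def test_separable_data_fit_perfectly(self):
        X, y = _gaussian_2class(gap=6.0)
        spec = BPNNSpec(input_size=3, epochs=200, seed=0)
        model = train_bpnn(spec, X, y)
        pred, _ = predict(model, X)
        assert np.mean(np.array(pred) == np.array(y)) == 1.0
        assert len(model.loss_history) == 200
        assert model.loss_history[-1] < model.loss_history[0]

    def test_zero_epochs_leaves_network_at_initialization(self):
        X, y = _gaussian_2class()
        spec = BPNNSpec(input_size=3, epochs=0, seed=3)
        model = train_bpnn(spec, X, y)
        fresh = MLP(spec)
        Xs = model.scaler.transform(X)
        assert np.allclose(model.model.predict_proba(Xs), fresh.predict_proba(Xs))
        assert model.loss_history == []

    def test_same_seed_identical_weights(self):
        X, y = _gaussian_2class()
        spec = BPNNSpec(input_size=3, epochs=30, seed=11)
        a = train_bpnn(spec, X, y)
        b = train_bpnn(spec, X, y)
        assert np.array_equal(a.model.get_flat(), b.model.get_flat())

    def test_nonfinite_loss_aborts(self):
        X, y = _gaussian_2class(n=20)
        spec = BPNNSpec(input_size=3, epochs=5, seed=0)
        net = MLP(spec)
        net.weights[0][:] = np.nan
        with pytest.raises(FloatingPointError):
            net.train(X, np.zeros(len(X), dtype=int))


class TestPSO:
    def test_sphere_benchmark(self):
        """Standard 10-D sphere: best fitness < 1e-2 in ≥9/10 seeds."""
        bounds = ((-5.0, 5.0),) * 10
        wins = 0
        for seed in range(10):
            cfg = PSOConfig(bounds=bounds, seed=seed)
            _, best, traj = pso_minimize(lambda x: float(np.sum(x**2)), cfg)
            assert traj == sorted(traj, reverse=True)  # monotone nonincreasing
            wins += best < 1e-2
        assert wins >= 9

    def test_1d_quadratic_recovers_optimum(self):
        cfg = PSOConfig(swarm_size=20, iterations=60, bounds=((0.0, 10.0),), seed=1)
        pos, best, _ = pso_minimize(lambda x: float((x[0] - 3.0) ** 2), cfg)
        assert abs(pos[0] - 3.0) < 0.05

    def test_zero_iterations_returns_initial_best(self):
        cfg = PSOConfig(swarm_size=15, iterations=0, bounds=((-1.0, 1.0),) * 3, seed=2)
        pos, best, traj = pso_minimize(lambda x: float(np.sum(x**2)), cfg)
        assert len(traj) == 1
        assert best == pytest.approx(float(np.sum(pos**2)))

    def test_nonfinite_fitness_penalized_not_fatal(self):
        def sometimes_nan(x):
            return np.nan if x[0] > 0 else float(x[0] ** 2)

        cfg = PSOConfig(swarm_size=10, iterations=20, bounds=((-2.0, 2.0),), seed=0)
        pos, best, _ = pso_minimize(sometimes_nan, cfg)
        assert np.isfinite(best)
        assert pos[0] <= 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            PSOConfig(w_start=0.4, w_end=0.9)
        with pytest.raises(ConfigError):
            PSOConfig(bounds=((1.0, 1.0),))


class TestPSOBPNN:
    def test_collapsed_bounds_fix_architecture(self):
        X, y = _gaussian_2class(n=60)
        model = train_pso_bpnn(
            X, y,
            pso_config=PSOConfig(swarm_size=3, iterations=2, seed=0),
            arch_bounds=((50.0, 50.0001), (50.0, 50.0001), (0.01, 0.0100001)),
            proxy_epochs=5, final_epochs=10, optimize_weights=False,
        )
        assert model.details["hidden_sizes"] == (50, 50)
        assert model.details["learning_rate"] == pytest.approx(0.01, rel=1e-3)

    def test_beats_or_matches_plain_bpnn(self, feature_table):
        """Paired-seed comparison on the synthetic scene: the optimized
        network should match or beat the fixed 50/50 network in holdout
        accuracy and final training loss in most seeds."""
        labeled = feature_table[feature_table["in_distribution"]]
        feats = [c for c in labeled.columns if c in ("B2", "B3", "B4", "B8", "NDVI", "GNDVI", "GLCM_ENT_B8", "GLCM_MEAN_B8")]
        X = labeled[feats].to_numpy()
        y = np.array(labeled["label"])
        acc_wins = loss_wins = n_seeds = 6
        acc_ok = loss_ok = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(X))
            cut = int(0.8 * len(X))
            tr, te = order[:cut], order[cut:]
            plain = train_bpnn(
                BPNNSpec(input_size=len(feats), epochs=120, seed=seed), X[tr], y[tr]
            )
            tuned = train_pso_bpnn(
                X[tr], y[tr],
                pso_config=PSOConfig(swarm_size=6, iterations=5, seed=seed),
                proxy_epochs=12, final_epochs=120, seed=seed,
            )
            pa = np.mean(np.array(predict(plain, X[te])[0]) == y[te])
            pb = np.mean(np.array(predict(tuned, X[te])[0]) == y[te])
            acc_ok += pb >= pa
            loss_ok += tuned.loss_history[-1] <= plain.loss_history[-1]
        assert acc_ok >= n_seeds - 2
        assert loss_ok >= n_seeds - 2


class TestPredict:
    def test_uniform_probabilities_break_toward_first_class(self):
        spec = BPNNSpec(input_size=2, epochs=0, seed=0)
        net = MLP(spec)
        net.set_flat(np.zeros(net.n_parameters))  # logits all zero → uniform
        model = TrainedClassifier(
            kind="BPNN", model=net, class_order=CLASS_ORDER, scaler=None,
            feature_names=("a", "b"),
        )
        labels, probs = predict(model, np.zeros((3, 2)))
        assert labels == ["Arbor"] * 3
        assert np.allclose(probs, 0.2)

    def test_probability_rows_sum_to_one(self):
        X, y = _gaussian_2class()
        for kind in ("RF", "SVM"):
            model = train_baseline(kind, X, y)
            _, probs = predict(model, X)
            assert probs.shape == (len(X), 5)
            assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_missing_feature_column_named(self):
        X, y = _gaussian_2class()
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        model = train_baseline("RF", df, y)
        with pytest.raises(FormatError, match="b"):
            predict(model, df[["a", "c"]])

    def test_save_load_roundtrip(self, tmp_path):
        X, y = _gaussian_2class()
        model = train_baseline("RF", X, y)
        path = tmp_path / "model.pkl"
        save_model(model, path)
        back = load_model(path)
        assert predict(back, X)[0] == predict(model, X)[0]
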