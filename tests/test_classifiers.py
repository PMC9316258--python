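import numpy as np
import pytest

import sagpred as sp
from sagpred.classifiers import ClassifierError


def separable_data(n=60, seed=2):
    """Two well-separated Gaussian blobs: linearly separable with margin."""
    rng = np.random.default_rng(seed)
    y = np.array([1, 0] * (n // 2))
    X = rng.normal(scale=0.3, size=(n, 5))
    X[:, 0] += np.where(y == 1, 3.0, -3.0)
    return X, y


class TestGridSearch:
    def test_single_point_grid(self):
        X, y = separable_data()
        config = sp.ModelConfig(
            family="svm",
            svm_grid={"cost": (1.0,), "gamma": ("scale",), "kernel": ("rbf",)},
        )
        best, table = sp.grid_search(X, y, config)
        assert best == {"cost": 1.0, "gamma": "scale", "kernel": "rbf"}
        assert len(table) == 1

    def test_table_is_exhaustive(self):
        X, y = separable_data()
        config = sp.ModelConfig(
            family="svm",
            svm_grid={"cost": (0.1, 1.0), "gamma": (0.01, "scale"), "kernel": ("rbf",)},
        )
        _, table = sp.grid_search(X, y, config)
        assert len(table) == 2 * 2 * 1

    def test_linear_kernel_beats_flat_rbf_on_separable_data(self):
        X, y = separable_data()
        config = sp.ModelConfig(
            family="svm",
            svm_grid={"cost": (1.0,), "gamma": (1e-6,), "kernel": ("linear", "rbf")},
        )
        best, table = sp.grid_search(X, y, config)
        assert best["kernel"] == "linear"
        scores = dict(zip(table["kernel"], table["mean_f1"]))
        assert scores["linear"] > scores["rbf"]

    def test_single_class_labels_rejected(self):
        X, _ = separable_data()
        with pytest.raises(ClassifierError, match="both classes"):
            sp.grid_search(X, np.ones(len(X), dtype=int), sp.ModelConfig())

    def test_nonfinite_features_rejected(self):
        X, y = separable_data()
        X[0, 0] = np.inf
        with pytest.raises(ClassifierError, match="non-finite"):
            sp.grid_search(X, y, sp.ModelConfig())


class TestTrainAndBundle:
    def test_training_f1_is_perfect_on_separable_data(self, svm_fixed_config):
        X, y = separable_data()
        bundle = sp.train(X, y, svm_fixed_config)
        preds = sp.predict_labels(bundle, X)
        c = sp.confusion(y, preds)
        assert sp.metrics(c).f1 == 1.0

    def test_bundle_round_trip_is_bitwise(self, tmp_path, svm_fixed_config):
        X, y = separable_data(n=80)
        bundle = sp.train(X[:60], y[:60], svm_fixed_config)
        s1 = sp.predict_scores(bundle, X[60:])
        path = tmp_path / "model.bundle"
        bundle.save(path)
        s2 = sp.predict_scores(sp.ModelBundle.load(path), X[60:])
        assert np.array_equal(s1, s2)

    def test_full_rank_pca_matches_no_pca_pipeline(self):
        # numeric gamma: the 'scale' heuristic depends on per-fold flattened
        # variance, which an orthonormal rotation does not exactly preserve
        config = sp.ModelConfig(
            family="svm", seed=17,
            fixed_params={"cost": 1.0, "gamma": 0.2, "kernel": "rbf"},
        )
        X, y = separable_data(n=40)
        plain = sp.train(X, y, config)
        rotated = sp.train(X, y, config, pca_dims=X.shape[1])
        s1 = sp.predict_scores(plain, X)
        s2 = sp.predict_scores(rotated, X)
        assert np.allclose(s1, s2, atol=1e-6)

    @pytest.mark.parametrize("family", ["svm", "gbt"])
    def test_determinism_and_row_permutation_invariance(self, family):
        X, y = separable_data(n=50, seed=7)
        config = sp.ModelConfig(
            family=family,
            seed=17,
            fixed_params=sp.ModelConfig(family=family).default_params(),
        )
        test_X = separable_data(n=20, seed=8)[0]
        b1 = sp.train(X, y, config)
        b2 = sp.train(X, y, config)
        assert np.array_equal(sp.predict_scores(b1, test_X), sp.predict_scores(b2, test_X))
        perm = np.random.default_rng(3).permutation(len(y))
        b3 = sp.train(X[perm], y[perm], config)
        assert np.abs(
            sp.predict_scores(b1, test_X) - sp.predict_scores(b3, test_X)
        ).max() <= 1e-9

    def test_label_flip_mirrors_scores(self, strong_features, svm_fixed_config):
        feats, y = strong_features
        X = feats.values
        b_pos = sp.train(X, y, svm_fixed_config)
        b_neg = sp.train(X, 1 - y, svm_fixed_config)
        s_pos = sp.predict_scores(b_pos, X)
        s_neg = sp.predict_scores(b_neg, X)
        assert np.abs(s_pos + s_neg - 1.0).max() <= 0.05

    def test_zero_variance_column_warns_not_errors(self, caplog, svm_fixed_config):
        X, y = separable_data(n=40)
        X[:, 3] = 2.0
        with caplog.at_level("WARNING", logger="sagpred.classifiers"):
            bundle = sp.train(X, y, svm_fixed_config)
        assert any("zero-variance" in m for m in caplog.messages)
        assert np.all(np.isfinite(sp.predict_scores(bundle, X)))

    def test_scores_are_probabilities_and_pure(self, svm_fixed_config):
        X, y = separable_data(n=40)
        bundle = sp.train(X, y, svm_fixed_config)
        doubled = np.vstack([X[:5], X[:5]])
        s = sp.predict_scores(bundle, doubled)
        assert np.all((s >= 0) & (s <= 1))
        assert np.array_equal(s[:5], s[5:])

    def test_width_mismatch_names_expected_columns(self, svm_fixed_config):
        X, y = separable_data(n=40)
        bundle = sp.train(X, y, svm_fixed_config)
        with pytest.raises(ClassifierError, match="5"):
            sp.predict_scores(bundle, X[:, :3])


class TestModelConfig:
    def test_grid_points_follow_declared_order(self):
        config = sp.ModelConfig(
            family="svm",
            svm_grid={"cost": (1.0, 2.0), "gamma": (0.1,), "kernel": ("linear", "rbf")},
        )
        points = config.grid_points()
        assert points[0] == {"cost": 1.0, "gamma": 0.1, "kernel": "linear"}
        assert points[1] == {"cost": 1.0, "gamma": 0.1, "kernel": "rbf"}
        assert len(points) == 4

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            sp.ModelConfig(family="svm", svm_grid={"cost": (), "gamma": (1,), "kernel": ("rbf",)})

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            sp.ModelConfig(family="forest")
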