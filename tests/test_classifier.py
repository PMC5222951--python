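"""Hidden-node selection, network training, prediction, and LOOCV."""

import numpy as np
import pandas as pd
import pytest

import fcdsurf as f
from fcdsurf.classifier import (VertexNetClassifier, loocv, network_predict,
                                select_hidden_nodes, single_feature_network,
                                train_network)


class TestSelectHiddenNodes:
    def test_independent_equal_variance_features_need_all(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4000, 28))  # 27/28 = 0.964 < 0.99
        assert select_hidden_nodes(X) == 28

    def test_rank_two_matrix_gives_two(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(500, 2))
        mix = rng.normal(size=(2, 26))
        X = np.c_[base, base @ mix]
        assert select_hidden_nodes(X) == 2

    def test_threshold_zero_gives_one(self):
        X = np.random.default_rng(2).normal(size=(100, 5))
        assert select_hidden_nodes(X, variance_threshold=0.0) == 1

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            select_hidden_nodes(np.zeros((50, 4)))


def _separable(n=400, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.normal(size=(n, 2)) + 6.0 * y[:, None]
    return X, y


class TestVertexNetClassifier:
    def test_separable_fixture_high_auc(self):
        X, y = _separable()
        clf = VertexNetClassifier(hidden_nodes=4, random_state=0).fit(X, y)
        p = clf.lesion_probability(X)
        _, _, auc = f.vertexwise_roc_auc(p, y)
        assert auc > 0.99

    def test_permuted_labels_chance_auc(self):
        rng = np.random.default_rng(3)
        aucs = []
        for seed in range(20):
            X = rng.normal(size=(600, 4))
            y = rng.integers(0, 2, 600)  # labels independent of features
            X_tr, y_tr, X_te, y_te = X[:400], y[:400], X[400:], y[400:]
            clf = VertexNetClassifier(hidden_nodes=3,
                                      random_state=seed).fit(X_tr, y_tr)
            _, _, auc = f.vertexwise_roc_auc(clf.lesion_probability(X_te),
                                             y_te)
            aucs.append(auc)
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_same_seed_bitwise_identical_weights(self):
        X, y = _separable(seed=4)
        a = VertexNetClassifier(hidden_nodes=5, random_state=7).fit(X, y)
        b = VertexNetClassifier(hidden_nodes=5, random_state=7).fit(X, y)
        for wa, wb in zip(a.net_.coefs_, b.net_.coefs_):
            assert np.array_equal(wa, wb)

    def test_single_class_labels_rejected(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="single class"):
            VertexNetClassifier().fit(X, np.ones(10))

    def test_probabilities_in_unit_interval(self):
        X, y = _separable(seed=5)
        clf = VertexNetClassifier(hidden_nodes=3, random_state=1).fit(X, y)
        p = clf.lesion_probability(np.random.default_rng(0).normal(
            size=(200, 2)) * 10)
        assert np.all((p >= 0) & (p <= 1))

    def test_feature_count_mismatch_rejected(self):
        X, y = _separable()
        clf = VertexNetClassifier(hidden_nodes=2, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="expected 2 features"):
            clf.predict_proba(np.zeros((5, 3)))

    def test_prediction_invariant_to_row_order(self):
        X, y = _separable(seed=6)
        clf = VertexNetClassifier(hidden_nodes=3, random_state=2).fit(X, y)
        perm = np.random.default_rng(1).permutation(len(X))
        np.testing.assert_allclose(clf.lesion_probability(X)[perm],
                                   clf.lesion_probability(X[perm]))

    def test_persisted_network_reproduces_probabilities(self):
        X, y = _separable(seed=7)
        clf = VertexNetClassifier(hidden_nodes=3, random_state=3).fit(X, y)
        model = clf.to_dict(feature_names=["a", "b"])
        np.testing.assert_allclose(network_predict(model, X),
                                   clf.lesion_probability(X), atol=1e-12)

    def test_balanced_flag_oversamples_minority(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 2))
        y = (np.arange(300) < 20).astype(int)
        clf = VertexNetClassifier(hidden_nodes=2, balanced=True,
                                  random_state=0)
        Xb, yb = clf._oversample(X, y)
        assert (yb == 1).sum() == (yb == 0).sum()


def _matrix_fixture(n_patients=4, n_vertices=60, seed=0, effect=4.0):
    """Small labelled feature matrix shaped like the assembly output."""
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_patients):
        for hemi in ("left", "right"):
            X = rng.normal(size=(n_vertices, 28))
            label = np.zeros(n_vertices, dtype=int) - 1
            if hemi == "left":
                label[:10] = 1
                X[:10, :4] += effect
                label[10:] = -1
            else:
                label[:] = 0
            df = pd.DataFrame(X, columns=list(f.CANONICAL_COLUMNS))
            df.insert(0, "subject", f"p{i}")
            df.insert(1, "group", "patient")
            df.insert(2, "hemisphere", hemi)
            df.insert(3, "vertex", np.arange(n_vertices))
            df["label"] = label
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


class TestLoocv:
    def test_one_fold_per_patient_and_no_leakage(self):
        m = _matrix_fixture()
        folds = loocv(m, hidden_nodes=3, seed=0)
        assert len(folds) == 4
        for fold in folds:
            assert fold.subject not in fold.train_subjects
            assert len(fold.train_subjects) == 3

    def test_needs_two_patients(self):
        m = _matrix_fixture(n_patients=1)
        with pytest.raises(ValueError, match="at least 2"):
            loocv(m, hidden_nodes=2, seed=0)

    def test_lesional_vertices_score_higher(self):
        m = _matrix_fixture(effect=5.0)
        folds = loocv(m, hidden_nodes=4, seed=0)
        for fold in folds:
            probs = fold.probabilities
            les = probs[(probs.hemisphere == "left") & (probs.vertex < 10)]
            healthy = probs[probs.hemisphere == "right"]
            assert les.probability.mean() > healthy.probability.mean()


class TestSingleFeatureNetwork:
    def _bimodal_matrix(self, seed=0):
        """Lesions extreme in BOTH directions of one feature."""
        rng = np.random.default_rng(seed)
        n = 400
        X = rng.normal(size=(n, 1))
        y = np.zeros(n, dtype=int)
        y[:60] = 1
        X[:30, 0] = rng.normal(5, 0.5, 30)
        X[30:60, 0] = rng.normal(-5, 0.5, 30)
        df = pd.DataFrame(X, columns=["thickness.z"])
        df.insert(0, "subject", "p0")
        df.insert(1, "group", "patient")
        df.insert(2, "hemisphere", "left")
        df.insert(3, "vertex", np.arange(n))
        df["label"] = y
        return df

    def test_two_nodes_beat_one_on_bimodal_abnormality(self):
        m = self._bimodal_matrix()
        X = m[["thickness.z"]].to_numpy()
        y = m["label"].to_numpy()
        two = single_feature_network(m, "thickness.z", seed=0)
        one = train_network(m, hidden_nodes=1, seed=0,
                            feature_columns=("thickness.z",))
        _, _, auc2 = f.vertexwise_roc_auc(two.lesion_probability(X), y)
        _, _, auc1 = f.vertexwise_roc_auc(one.lesion_probability(X), y)
        assert auc2 > 0.9
        assert auc1 < 0.8

    def test_monotone_fixture_high_auc(self):
        rng = np.random.default_rng(1)
        n = 400
        X = rng.normal(size=(n, 1))
        y = np.zeros(n, dtype=int)
        y[:50] = 1
        X[:50, 0] += 4.0
        m = pd.DataFrame(X, columns=["lcd.z"])
        m.insert(0, "subject", "p0")
        m.insert(1, "group", "patient")
        m.insert(2, "hemisphere", "left")
        m.insert(3, "vertex", np.arange(n))
        m["label"] = y
        net = single_feature_network(m, "lcd.z", seed=0)
        _, _, auc = f.vertexwise_roc_auc(net.lesion_probability(X), y)
        assert auc > 0.95

    def test_same_seed_determinism(self):
        m = self._bimodal_matrix()
        a = single_feature_network(m, "thickness.z", seed=5)
        b = single_feature_network(m, "thickness.z", seed=5)
        for wa, wb in zip(a.net_.coefs_, b.net_.coefs_):
            assert np.array_equal(wa, wb)
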