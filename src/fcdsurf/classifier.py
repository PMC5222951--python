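"""Vertexwise lesion classifier: a single-hidden-layer feedforward network.

The network topology follows the detection method: one hidden layer whose
size is chosen by a PCA on the control cohort (number of components
explaining > 99% of the variance), logistic activations, and an output in
[0, 1] read as the probability that a vertex is lesional.  Training uses
only labelled rows (lesional = 1, contralateral healthy = 0); evaluation is
leave-one-out over patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.decomposition import PCA
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .normalization import CANONICAL_COLUMNS, training_view

SCHEMA_VERSION = 1


def select_hidden_nodes(control_X: np.ndarray,
                        variance_threshold: float = 0.99,
                        standardize: bool = True) -> int:
    """Smallest number of principal components explaining more than
    ``variance_threshold`` of the control-cohort feature variance."""
    X = np.asarray(control_X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError(f"need a 2D control matrix with >= 2 rows, "
                         f"got shape {X.shape}")
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.all(sd <= 0):
            raise ValueError("degenerate control matrix: zero variance")
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("degenerate control matrix: zero variance")
    pca = PCA(n_components=min(X.shape))
    pca.fit(X)
    cum = np.cumsum(pca.explained_variance_ratio_)
    above = np.flatnonzero(cum > variance_threshold)
    return int(above[0]) + 1 if len(above) else int(len(cum))


class VertexNetClassifier(BaseEstimator, ClassifierMixin):
    """Seeded single-hidden-layer network over standardized vertex features.

    Parameters
    ----------
    hidden_nodes : int
        Hidden-layer width (use :func:`select_hidden_nodes` for the PCA
        rule; single-feature networks use 2 to capture abnormality in both
        directions).
    max_iter : int or "auto"
        Training epochs.  "auto" targets a fixed total number of gradient
        updates, so small fixtures get many epochs and large vertex tables
        get few.
    learning_rate_init, tol : optimizer settings (Adam).
    balanced : bool
        If True, oversample the minority class (seeded) to balance the
        lesional/healthy row counts.  Default False: train on the raw,
        imbalanced rows.
    random_state : int
        Seed; identical (data, params, seed) gives identical weights.
    """

    def __init__(self, hidden_nodes: int = 10, max_iter: int | str = "auto",
                 learning_rate_init: float = 1e-3, tol: float = 1e-5,
                 balanced: bool = False, random_state: int = 0):
        self.hidden_nodes = hidden_nodes
        self.max_iter = max_iter
        self.learning_rate_init = learning_rate_init
        self.tol = tol
        self.balanced = balanced
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2D with one label per row")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError(f"training labels contain a single class "
                             f"{classes.tolist()}; need both 0 and 1")
        if self.hidden_nodes < 1:
            raise ValueError("hidden_nodes must be >= 1")
        if self.balanced:
            X, y = self._oversample(X, y)
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        batch = min(512, len(X))
        if self.max_iter == "auto":
            n_batches = max(1, int(np.ceil(len(X) / batch)))
            epochs = int(np.clip(np.ceil(4000 / n_batches), 100, 3000))
        else:
            epochs = int(self.max_iter)
        self.net_ = MLPClassifier(
            hidden_layer_sizes=(int(self.hidden_nodes),),
            activation="logistic", solver="adam",
            learning_rate_init=self.learning_rate_init,
            batch_size=batch,
            max_iter=epochs, tol=self.tol, shuffle=True,
            random_state=self.random_state)
        import warnings
        from sklearn.exceptions import ConvergenceWarning
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.net_.fit(Xs, y.astype(np.int64))
        self.classes_ = self.net_.classes_
        self.n_features_in_ = X.shape[1]
        self.loss_ = float(self.net_.loss_)
        return self

    def _oversample(self, X, y):
        rng = np.random.default_rng(self.random_state)
        counts = {c: int((y == c).sum()) for c in np.unique(y)}
        n_max = max(counts.values())
        parts_X, parts_y = [X], [y]
        for c, n in counts.items():
            if n < n_max:
                extra = rng.choice(np.flatnonzero(y == c), size=n_max - n,
                                   replace=True)
                parts_X.append(X[extra])
                parts_y.append(y[extra])
        return np.concatenate(parts_X), np.concatenate(parts_y)

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, "
                             f"got {X.shape[1]}")
        return self.net_.predict_proba(self.scaler_.transform(X))

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def lesion_probability(self, X) -> np.ndarray:
        """P(lesional) per row, in [0, 1]."""
        return self.predict_proba(X)[:, list(self.classes_).index(1)]

    # -- portable persistence -------------------------------------------
    def to_dict(self, feature_names: list[str] | None = None) -> dict:
        check_is_fitted(self, "net_")
        return {
            "schema_version": SCHEMA_VERSION,
            "feature_names": list(feature_names) if feature_names else None,
            "hidden_nodes": int(self.hidden_nodes),
            "random_state": int(self.random_state),
            "scaler_mean": self.scaler_.mean_.tolist(),
            "scaler_scale": self.scaler_.scale_.tolist(),
            "coefs": [c.tolist() for c in self.net_.coefs_],
            "intercepts": [b.tolist() for b in self.net_.intercepts_],
            "loss": self.loss_,
            "n_iter": int(self.net_.n_iter_),
        }


def network_predict(model: dict, X: np.ndarray) -> np.ndarray:
    """Forward pass of a persisted network dict: P(lesional) per row."""
    if model.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {model.get('schema_version')}")
    X = np.asarray(X, dtype=np.float64)
    Xs = (X - np.asarray(model["scaler_mean"])) / np.asarray(model["scaler_scale"])
    w0, w1 = (np.asarray(c) for c in model["coefs"])
    b0, b1 = (np.asarray(b) for b in model["intercepts"])
    h = 1.0 / (1.0 + np.exp(-(Xs @ w0 + b0)))  # logistic hidden layer
    z = h @ w1 + b1
    return (1.0 / (1.0 + np.exp(-z))).ravel()


def train_network(matrix: pd.DataFrame, hidden_nodes: int, seed: int = 0,
                  feature_columns: tuple[str, ...] = CANONICAL_COLUMNS,
                  balanced: bool = False) -> VertexNetClassifier:
    """Fit the network on the labelled rows of a feature matrix."""
    train = training_view(matrix)
    X = train[list(feature_columns)].to_numpy()
    y = train["label"].to_numpy()
    clf = VertexNetClassifier(hidden_nodes=hidden_nodes, random_state=seed,
                              balanced=balanced)
    return clf.fit(X, y)


def single_feature_network(matrix: pd.DataFrame, feature: str, seed: int = 0
                           ) -> VertexNetClassifier:
    """2-hidden-node network on one feature (sensitive to high AND low)."""
    return train_network(matrix, hidden_nodes=2, seed=seed,
                         feature_columns=(feature,))


@dataclass
class LoocvFold:
    """One leave-one-out fold: probabilities for the held-out patient."""

    subject: str
    train_subjects: list[str]
    probabilities: pd.DataFrame  # columns: hemisphere, vertex, probability
    detection: object | None = None
    model: VertexNetClassifier | None = field(default=None, repr=False)


def loocv(matrix: pd.DataFrame, hidden_nodes: int, seed: int = 0,
          feature_columns: tuple[str, ...] = CANONICAL_COLUMNS,
          balanced: bool = False, detector=None,
          keep_models: bool = False) -> list[LoocvFold]:
    """Leave-one-patient-out cross-validation.

    For each patient (rows with ``group == "patient"``) a network is trained
    on every other patient's labelled rows and applied to all cortex
    vertices of the held-out patient.  ``detector``, if given, is called as
    ``detector(subject_id, probabilities)`` and its result stored per fold.
    Control rows never enter training (they only shape the normalization
    and the PCA node count upstream).
    """
    patients = sorted(matrix.loc[matrix["group"] == "patient", "subject"]
                      .unique())
    if len(patients) < 2:
        raise ValueError("leave-one-out needs at least 2 patients")
    folds = []
    for held_out in patients:
        train_rows = matrix[(matrix["group"] == "patient") &
                            (matrix["subject"] != held_out)]
        clf = VertexNetClassifier(hidden_nodes=hidden_nodes,
                                  random_state=seed, balanced=balanced)
        tv = training_view(train_rows)
        clf.fit(tv[list(feature_columns)].to_numpy(),
                tv["label"].to_numpy())
        test_rows = matrix[matrix["subject"] == held_out]
        prob = clf.lesion_probability(
            test_rows[list(feature_columns)].to_numpy())
        prob_df = pd.DataFrame({
            "hemisphere": test_rows["hemisphere"].to_numpy(),
            "vertex": test_rows["vertex"].to_numpy(),
            "probability": prob,
        })
        fold = LoocvFold(
            subject=held_out,
            train_subjects=sorted(tv["subject"].unique()),
            probabilities=prob_df,
            model=clf if keep_models else None)
        if detector is not None:
            fold.detection = detector(held_out, prob_df)
        folds.append(fold)
    return folds
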