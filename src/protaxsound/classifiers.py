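"""Probabilistic base classifiers whose outputs become calibration predictors.

Two interchangeable sources of per-species class probabilities:

* :class:`XCorrRandomForest` — a random forest over cross-correlation
  template scores.  Probabilities are tree vote fractions and deliberately
  uncalibrated; calibrating them is the job of the multinomial model.
* :class:`MelPatchCNN` — a small convolutional network over fixed-size mel
  log-power patches, with patch-level softmax outputs averaged to one
  sample-level distribution.

Anything exposing ``classes_`` and ``predict_proba`` returning a valid
probability simplex can stand in for either of them as a predictor source.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .nn import SmallConvNet

__all__ = ["XCorrRandomForest", "MelPatchCNN", "validate_probabilities"]


def validate_probabilities(p: np.ndarray, n_classes: int, tol: float = 1e-6) -> np.ndarray:
    """Assert the class-probability contract: shape, range, unit sum."""
    p = np.asarray(p, dtype=np.float64)
    if p.shape[-1] != n_classes:
        raise ValueError(f"expected {n_classes} class probabilities, got {p.shape[-1]}")
    if np.any(p < -tol) or np.any(p > 1 + tol):
        raise ValueError("probabilities outside [0, 1]")
    sums = p.sum(axis=-1)
    if np.any(np.abs(sums - 1.0) > 1e-3):
        raise ValueError("probabilities do not sum to 1")
    return np.clip(p, 0.0, 1.0)


class XCorrRandomForest(BaseEstimator, ClassifierMixin):
    """Random forest on cross-correlation feature vectors.

    Defaults: 500 fully grown trees, sqrt(p) features per split.  With pure
    leaves the averaged tree probabilities equal the fraction of trees voting
    for each class.
    """

    def __init__(self, n_estimators: int = 500, max_features: str = "sqrt",
                 oob_score: bool = False, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.oob_score = oob_score
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 classes to train the forest")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in feature matrix")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            oob_score=self.oob_score,
            random_state=self.random_state,
            n_jobs=1,
        ).fit(X, y)
        self.classes_ = self.forest_.classes_
        self.n_features_in_ = X.shape[1]
        self.feature_importances_ = self.forest_.feature_importances_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "forest_")
        X = np.asarray(X, dtype=np.float64)
        if X.shape[-1] != self.n_features_in_:
            raise ValueError(
                f"feature vector length {X.shape[-1]} does not match the "
                f"{self.n_features_in_} cross-correlation features seen in training"
            )
        return validate_probabilities(self.forest_.predict_proba(X), self.classes_.size)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=-1)]


class MelPatchCNN(BaseEstimator, ClassifierMixin):
    """Convolutional classifier over mel log-power patches.

    ``fit`` consumes an (n_patches, n_mels, n_frames) array with one label
    per patch.  Prediction aggregates patch softmax distributions to one
    sample-level distribution by their mean.
    """

    def __init__(self, filters=(8, 16), epochs: int = 30, batch_size: int = 32,
                 lr: float = 1e-2, time_downsample: int = 2, random_state: int = 0):
        self.filters = filters
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.time_downsample = time_downsample
        self.random_state = random_state

    def _downsample(self, X: np.ndarray) -> np.ndarray:
        """Average consecutive frame pairs: cheap time decimation of patches."""
        d = self.time_downsample
        if d <= 1:
            return X
        t = (X.shape[-1] // d) * d
        return X[..., :t].reshape(*X.shape[:-1], t // d, d).mean(axis=-1)

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("X must be (n_patches, n_mels, n_frames)")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes to train the network")
        self.patch_shape_ = X.shape[1:]
        X = self._downsample(X)
        self._mu = float(X.mean())
        self._sd = float(X.std() + 1e-6)
        Xn = ((X - self._mu) / self._sd)[:, None, :, :]
        rng = np.random.default_rng(self.random_state)
        net = SmallConvNet(self.classes_.size, X.shape[1:], filters=self.filters, rng=rng)
        n = Xn.shape[0]
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for i in range(0, n, self.batch_size):
                idx = order[i : i + self.batch_size]
                loss, grads = net.loss_and_grads(Xn[idx], y_idx[idx])
                net.adam_step(grads, lr=self.lr)
                epoch_loss += loss * idx.size
            self.loss_curve_.append(epoch_loss / n)
        self.net_ = net
        return self

    def _check_patches(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches, dtype=np.float32)
        if patches.ndim == 2:
            patches = patches[None]
        if patches.shape[0] == 0:
            raise ValueError("empty patch set")
        if patches.shape[1:] != self.patch_shape_:
            raise ValueError(
                f"patch shape {patches.shape[1:]} != training shape {self.patch_shape_}"
            )
        patches = self._downsample(patches)
        return ((patches - self._mu) / self._sd)[:, None, :, :]

    def predict_proba_patches(self, patches):
        """Per-patch softmax distributions, (n_patches, n_classes)."""
        check_is_fitted(self, "net_")
        return validate_probabilities(
            self.net_.predict_proba(self._check_patches(patches)), self.classes_.size
        )

    def predict_proba(self, patches):
        """Sample-level distribution: mean of patch softmaxes, renormalized."""
        p = self.predict_proba_patches(patches).mean(axis=0)
        p /= p.sum()
        return validate_probabilities(p, self.classes_.size)

    def predict(self, patches):
        return self.classes_[int(np.argmax(self.predict_proba(patches)))]
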