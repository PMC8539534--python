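"""The two per-pixel prediction models as scikit-learn style estimators.

* :class:`TissueDamageSegmenter` (TDSM) — 3-class classifier of laser-induced
  damage (no damage / ring / thermo) from an ``l x w x w`` spectral patch,
  trained with inverse-frequency weighted cross-entropy.
* :class:`PeakTemperatureRegressor` (PTPM) — regressor of the peak
  temperature (degC) reached at the patch centre, trained with the mean
  relative error loss.

Both share one small 3-D spectral CNN backbone and the training recipe:
plain SGD, learning rate 0.001, strict batch size 1, 5 epochs, seeded
per-epoch shuffling.  They compose with sklearn pipelines/model selection;
patch input is accepted as ``(n, l, w, w)`` or flattened ``(n, l*w*w)``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .io import EXCLUDED, Hypercube
from .dataset import extract_patch


class _BaseSpectralCNN(BaseEstimator):
    """Shared fit machinery for the two patch CNNs."""

    def __init__(
        self,
        n_bands: int = 100,
        patch_width: int = 5,
        lr: float = 0.001,
        epochs: int = 5,
        batch_size: int = 1,
        shuffle: bool = True,
        random_state: int = 0,
    ):
        self.n_bands = n_bands
        self.patch_width = patch_width
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.shuffle = shuffle
        self.random_state = random_state

    # -- input handling -----------------------------------------------------
    def _as_patches(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        l, w = self.n_bands, self.patch_width
        if X.ndim == 2:
            if X.shape[1] != l * w * w:
                raise ValueError(
                    f"flattened input has {X.shape[1]} features, expected {l * w * w}"
                )
            X = X.reshape(-1, l, w, w)
        elif X.ndim == 4:
            if X.shape[1:] != (l, w, w):
                raise ValueError(f"patch shape {X.shape[1:]} != {(l, w, w)}")
        else:
            raise ValueError("X must be (n, l, w, w) patches or flattened 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("patches must be finite")
        return X

    def _n_outputs(self) -> int:
        raise NotImplementedError

    def _sample_loss(self, logits, target):
        """Return (loss, dloss/dlogits) for one sample."""
        raise NotImplementedError

    def _fit_common(self, X: np.ndarray, y: np.ndarray) -> None:
        if self.batch_size != 1:
            raise ValueError("training is strict single-sample SGD (batch_size=1)")
        if len(X) == 0:
            raise ValueError("empty training set")
        rng = np.random.default_rng(self.random_state)
        self.spec_ = nn.spectral_cnn_spec(
            self._n_outputs(), l=self.n_bands, w=self.patch_width
        )
        self.model_ = nn.SpectralCNN(self.spec_, rng=rng)
        self._init_head(y)
        n = len(X)
        loss_log = []
        order = np.arange(n)
        for _epoch in range(self.epochs):
            if self.shuffle:
                rng.shuffle(order)
            for i in order:
                logits = self.model_.forward(X[i : i + 1], train=True)
                loss, dlogits = self._sample_loss(logits.ravel(), y[i])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at iteration {len(loss_log)}: {loss}"
                    )
                self.model_.backward(dlogits.reshape(1, -1))
                self.model_.sgd_step(self.lr)
                loss_log.append(loss)
        self.loss_log_ = np.asarray(loss_log)
        self.n_iter_ = len(loss_log)
        self.n_features_in_ = self.n_bands * self.patch_width**2

    def _init_head(self, y: np.ndarray) -> None:
        pass

    def _forward_batched(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        outs = [
            self.model_.forward(X[i : i + batch]) for i in range(0, len(X), batch)
        ]
        return np.concatenate(outs, axis=0)

    # -- checkpointing ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Flat parameter archive (.npz) + architecture/params JSON sidecar."""
        check_is_fitted(self, "model_")
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.model_.state_dict())
        meta = {
            "estimator": type(self).__name__,
            "params": self.get_params(),
        }
        if hasattr(self, "classes_"):
            meta["classes"] = np.asarray(self.classes_).tolist()
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "_BaseSpectralCNN":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        est = cls(**meta["params"])
        est.spec_ = nn.spectral_cnn_spec(
            est._n_outputs(), l=est.n_bands, w=est.patch_width
        )
        est.model_ = nn.SpectralCNN(est.spec_, rng=0)
        with np.load(path.with_suffix(".npz")) as archive:
            est.model_.load_state_dict(dict(archive))
        if "classes" in meta:
            est.classes_ = np.asarray(meta["classes"])
        est.n_features_in_ = est.n_bands * est.patch_width**2
        return est


class TissueDamageSegmenter(ClassifierMixin, _BaseSpectralCNN):
    """3-class tissue-damage classifier (TDSM).

    Class imbalance (healthy tissue dominates the ROI) is handled with
    inverse-frequency cross-entropy weights, normalised so they sum to the
    number of classes.
    """

    N_CLASSES = 3

    def __init__(
        self,
        n_bands: int = 100,
        patch_width: int = 5,
        lr: float = 0.001,
        epochs: int = 5,
        batch_size: int = 1,
        shuffle: bool = True,
        random_state: int = 0,
        class_weight: str | None = "inverse_frequency",
    ):
        super().__init__(n_bands, patch_width, lr, epochs, batch_size, shuffle, random_state)
        self.class_weight = class_weight

    def _n_outputs(self) -> int:
        return self.N_CLASSES

    def _sample_loss(self, logits, target):
        return nn.weighted_cross_entropy(logits, int(target), self.class_weights_)

    def fit(self, X, y):
        X = self._as_patches(X)
        y = np.asarray(y, dtype=int)
        if np.any((y < 0) | (y >= self.N_CLASSES)):
            raise ValueError(f"labels must be in 0..{self.N_CLASSES - 1}")
        self.classes_ = np.arange(self.N_CLASSES)
        if self.class_weight == "inverse_frequency":
            self.class_weights_ = nn.inverse_frequency_weights(y, self.N_CLASSES)
        elif self.class_weight is None:
            self.class_weights_ = np.ones(self.N_CLASSES)
        else:
            raise ValueError(f"unknown class_weight {self.class_weight!r}")
        self._fit_common(X, y)
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        return self._forward_batched(self._as_patches(X))

    def predict_proba(self, X):
        z = self.decision_function(X)
        z = z - z.max(axis=1, keepdims=True)
        p = np.exp(z)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


class PeakTemperatureRegressor(RegressorMixin, _BaseSpectralCNN):
    """Per-pixel peak-temperature regressor (PTPM), mean-relative-error loss.

    Targets below ``min_target`` (1 degC) are rejected — the relative-error
    loss is ill-conditioned near zero, and tissue baseline is 36 degC so the
    bound never binds on valid data.  The FC bias starts at the mean training
    target so the optimisation begins in a sane relative-error regime.
    """

    def __init__(
        self,
        n_bands: int = 100,
        patch_width: int = 5,
        lr: float = 0.001,
        epochs: int = 5,
        batch_size: int = 1,
        shuffle: bool = True,
        random_state: int = 0,
        min_target: float = 1.0,
    ):
        super().__init__(n_bands, patch_width, lr, epochs, batch_size, shuffle, random_state)
        self.min_target = min_target

    def _n_outputs(self) -> int:
        return 1

    def _sample_loss(self, logits, target):
        return nn.mean_relative_error(logits, target, eps=self.min_target)

    def _init_head(self, y: np.ndarray) -> None:
        self.model_.layers[-1].bias[:] = float(np.mean(y))

    def fit(self, X, y):
        X = self._as_patches(X)
        y = np.asarray(y, dtype=np.float64)
        if np.any(y < self.min_target):
            raise ValueError(f"peak-temperature targets must be >= {self.min_target} degC")
        self._fit_common(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self._forward_batched(self._as_patches(X)).ravel()


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------


def build_model(kind: str, **kwargs):
    """``'tdsm'`` -> :class:`TissueDamageSegmenter`, ``'ptpm'`` ->
    :class:`PeakTemperatureRegressor`."""
    kinds = {"tdsm": TissueDamageSegmenter, "ptpm": PeakTemperatureRegressor}
    if kind not in kinds:
        raise ValueError(f"kind must be one of {sorted(kinds)}")
    return kinds[kind](**kwargs)


def loss_tdsm(logits, class_label, class_weights):
    """Weighted cross-entropy loss value for one sample."""
    return nn.weighted_cross_entropy(logits, class_label, class_weights)[0]


def loss_ptpm(pred, actual, eps: float = 1.0):
    """Mean relative error over a batch of (pred, actual) pairs."""
    return nn.mean_relative_error(pred, actual, eps=eps)[0]


def train(model, X, y, seed: int | None = None):
    """Fit *model* on the training split (optionally reseeding) and return it."""
    if seed is not None:
        model.set_params(random_state=seed)
    return model.fit(X, y)


def predict_map(
    model,
    cube: Hypercube | np.ndarray,
    roi_mask: np.ndarray,
    excluded_mask: np.ndarray | None = None,
    batch: int = 1024,
) -> np.ndarray:
    """Per-pixel prediction over ``ROI \\ excluded``.

    Returns a full-frame map: class codes with ``EXCLUDED`` elsewhere for a
    classifier, degC with NaN elsewhere for a regressor.
    """
    data = cube.data if isinstance(cube, Hypercube) else np.asarray(cube)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if excluded_mask is None:
        excluded_mask = np.zeros_like(roi_mask)
    effective = roi_mask & ~np.asarray(excluded_mask, dtype=bool)
    if not effective.any():
        raise ValueError("effective ROI is empty (everything excluded)")
    ys, xs = np.nonzero(effective)
    w = model.patch_width
    patches = np.stack([extract_patch(data, (x, y), w) for y, x in zip(ys, xs)])
    is_classifier = hasattr(model, "classes_")
    if is_classifier:
        out = np.full(roi_mask.shape, EXCLUDED, dtype=np.uint8)
    else:
        out = np.full(roi_mask.shape, np.nan, dtype=np.float64)
    for i in range(0, len(patches), batch):
        pred = model.predict(patches[i : i + batch])
        out[ys[i : i + batch], xs[i : i + batch]] = pred
    return out
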