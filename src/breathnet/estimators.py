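"""Sklearn-style estimators wrapping the convolutional breathing models.

Both estimators follow scikit-learn conventions: all constructor arguments
are stored verbatim, fitting populates trailing-underscore attributes, and
``get_params``/``set_params`` come from :class:`sklearn.base.BaseEstimator`,
so the models compose with sklearn pipelines and model selection.

Inputs may be given either as ``(n_samples, n_timesteps, 12)`` arrays or as
flattened ``(n_samples, n_timesteps * 12)`` feature matrices (e.g. the
7-s window yields 875 x 12 = 10,500 features); flattened input is reshaped
internally.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .channels import CLASSES, default_channel_names
from .configs import ClassifierConfig, DetectorConfig
from .metrics import classification_report
from .models import build_classifier, build_detector, train_model


def _as_3d(x: np.ndarray, n_timesteps: int, n_channels: int = 12) -> np.ndarray:
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2 and x.shape[1] == n_timesteps * n_channels:
        x = x.reshape(x.shape[0], n_timesteps, n_channels)
    if x.ndim != 3 or x.shape[1] != n_timesteps or x.shape[2] != n_channels:
        raise ValueError(
            f"expected input of shape (n, {n_timesteps}, {n_channels}) or "
            f"(n, {n_timesteps * n_channels}), got {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    return x


def _resolve_mask(channel_mask) -> np.ndarray | None:
    """Channel mask as indices; accepts names, indices, or None (= all 12)."""
    if channel_mask is None:
        return None
    names = default_channel_names()
    idx = []
    for ch in channel_mask:
        idx.append(names.index(ch) if isinstance(ch, str) else int(ch))
    if not idx:
        raise ValueError("channel_mask must keep at least one channel")
    return np.asarray(sorted(set(idx)), dtype=int)


class _CNNBase(BaseEstimator):
    """Shared standardization and channel-mask plumbing."""

    def _prepare(self, x: np.ndarray, fit_stats: bool) -> np.ndarray:
        if self.mask_ is not None:
            x = x.copy()
            drop = np.setdiff1d(np.arange(x.shape[2]), self.mask_)
            x[:, :, drop] = 0.0  # masked channels are zeroed, keeping 12 inputs
        if not self.standardize:
            return x
        if fit_stats:
            self.channel_means_ = x.mean(axis=(0, 1))
            sd = x.std(axis=(0, 1))
            self.channel_stds_ = np.where(sd > 1e-12, sd, 1.0)
        return (x - self.channel_means_) / self.channel_stds_


class BreathingEventClassifier(_CNNBase, ClassifierMixin):
    """Window classifier: 6 conv + 4 fully connected layers over 7-s windows.

    ``mode='binary'`` trains a sigmoid head for a two-class problem (e.g.
    CSA vs normal breathing); ``mode='multi'`` a softmax head over the six
    breathing-event classes. ``scale`` picks the paper-size or desk-size
    architecture preset unless an explicit ``config`` is given.
    """

    def __init__(
        self,
        mode: str = "multi",
        scale: str = "desk",
        config: ClassifierConfig | None = None,
        epochs: int = 30,
        batch_size: int = 32,
        lr: float | None = None,
        validation_fraction: float = 0.15,
        channel_mask=None,
        standardize: bool = True,
        seed: int = 0,
        verbose: int = 0,
    ) -> None:
        self.mode = mode
        self.scale = scale
        self.config = config
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.validation_fraction = validation_fraction
        self.channel_mask = channel_mask
        self.standardize = standardize
        self.seed = seed
        self.verbose = verbose

    def _make_config(self) -> ClassifierConfig:
        if self.config is not None:
            return self.config
        factory = ClassifierConfig.desk if self.scale == "desk" else ClassifierConfig.paper
        return factory(output=self.mode)

    def fit(self, X, y):
        config = self._make_config()
        self.config_ = config
        self.mask_ = _resolve_mask(self.channel_mask)
        x = _as_3d(X, config.window_samples)
        y = np.asarray(y)
        if y.shape[0] != x.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        self.classes_ = np.unique(y)
        if self.mode == "binary" and len(self.classes_) != 2:
            raise ValueError(
                f"binary mode needs exactly 2 classes, got {len(self.classes_)}"
            )
        class_index = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([class_index[v] for v in y])

        x = self._prepare(x, fit_stats=True)
        rng = np.random.default_rng(self.seed)
        n_val = int(round(self.validation_fraction * x.shape[0]))
        perm = rng.permutation(x.shape[0])
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        if config.output == "binary":
            y_train = y_idx[train_idx].astype(np.float64)
            y_val = y_idx[val_idx].astype(np.float64)
        else:
            y_train, y_val = y_idx[train_idx], y_idx[val_idx]

        net = build_classifier(config, seed=self.seed)
        lr = self.lr if self.lr is not None else config.lr
        self.model_ = train_model(
            net, x[train_idx], y_train,
            x[val_idx] if n_val else None, y_val if n_val else None,
            epochs=self.epochs, batch_size=self.batch_size,
            optimizer=config.optimizer, lr=lr, seed=self.seed,
            architecture=f"classifier-{self.mode}-{config.scale}",
            verbose=self.verbose,
        )
        self.history_ = self.model_.history
        self.n_features_in_ = config.window_samples * 12
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        x = self._prepare(_as_3d(X, self.config_.window_samples), fit_stats=False)
        p = self.model_.network.predict_proba(x, batch_size=max(self.batch_size, 16))
        if self.config_.output == "binary":
            p = p.reshape(-1, 1)
            return np.hstack([1 - p, p])
        return p

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def decision_scores(self, X) -> np.ndarray:
        """Probability of ``classes_[1]`` (binary mode) for ROC analysis."""
        check_is_fitted(self, "model_")
        if self.config_.output != "binary":
            raise ValueError("decision_scores is defined for binary mode only")
        return self.predict_proba(X)[:, 1]


class BreathingEventDetector(_CNNBase):
    """Per-second residual detector: 30-s segment in, 30 labels out.

    A wide initial convolution followed by four residual blocks (widths
    doubling from ``base_filters``) downsample time by a factor of 125, and
    a time-distributed softmax head emits a six-class probability row for
    every second. ``fit`` takes ``X`` of shape ``(n, segment_s*125, 12)``
    and ``Y`` of per-second labels ``(n, segment_s)`` (strings or indices
    into the six-class vocabulary).
    """

    classes_: np.ndarray

    def __init__(
        self,
        scale: str = "desk",
        config: DetectorConfig | None = None,
        epochs: int = 20,
        batch_size: int = 16,
        lr: float | None = None,
        validation_fraction: float = 0.15,
        channel_mask=None,
        standardize: bool = True,
        seed: int = 0,
        verbose: int = 0,
    ) -> None:
        self.scale = scale
        self.config = config
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.validation_fraction = validation_fraction
        self.channel_mask = channel_mask
        self.standardize = standardize
        self.seed = seed
        self.verbose = verbose

    def _make_config(self) -> DetectorConfig:
        if self.config is not None:
            return self.config
        return DetectorConfig.desk() if self.scale == "desk" else DetectorConfig.paper()

    @staticmethod
    def _labels_to_idx(Y: np.ndarray) -> np.ndarray:
        if Y.dtype.kind in "iu":
            return Y.astype(np.int64)
        lut = {c: i for i, c in enumerate(CLASSES)}
        try:
            return np.vectorize(lut.__getitem__)(Y).astype(np.int64)
        except KeyError as err:
            raise ValueError(f"unknown label {err.args[0]!r}") from None

    def fit(self, X, Y):
        config = self._make_config()
        self.config_ = config
        self.mask_ = _resolve_mask(self.channel_mask)
        x = _as_3d(X, config.input_samples)
        y = self._labels_to_idx(np.asarray(Y))
        if y.shape != (x.shape[0], config.per_second_outputs):
            raise ValueError(
                f"Y must have shape (n, {config.per_second_outputs}), got {y.shape}"
            )
        self.classes_ = np.asarray(CLASSES)
        x = self._prepare(x, fit_stats=True)
        rng = np.random.default_rng(self.seed)
        n_val = int(round(self.validation_fraction * x.shape[0]))
        perm = rng.permutation(x.shape[0])
        val_idx, train_idx = perm[:n_val], perm[n_val:]

        net = build_detector(config, seed=self.seed)
        lr = self.lr if self.lr is not None else config.lr
        self.model_ = train_model(
            net, x[train_idx], y[train_idx],
            x[val_idx] if n_val else None, y[val_idx] if n_val else None,
            epochs=self.epochs, batch_size=self.batch_size,
            optimizer=config.optimizer, lr=lr, seed=self.seed,
            plateau_patience=config.plateau_patience,
            plateau_factor=config.plateau_factor,
            architecture=f"detector-{config.scale}",
            verbose=self.verbose,
        )
        if self.standardize:
            self.model_.extra["channel_means"] = self.channel_means_.tolist()
            self.model_.extra["channel_stds"] = self.channel_stds_.tolist()
        self.history_ = self.model_.history
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        x = self._prepare(_as_3d(X, self.config_.input_samples), fit_stats=False)
        return self.model_.network.predict_proba(x, batch_size=max(self.batch_size, 8))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=2)]

    def score(self, X, Y) -> float:
        """Mean per-second accuracy."""
        y_true = self._labels_to_idx(np.asarray(Y))
        y_pred = self._labels_to_idx(self.predict(X))
        return float((y_true == y_pred).mean())

    def second_level_report(self, X, Y):
        """Full per-second classification report on flattened seconds."""
        y_pred = self.predict(X).ravel()
        y_true = np.asarray(Y).ravel()
        if y_true.dtype.kind in "iu":
            y_true = np.asarray(CLASSES)[y_true]
        return classification_report(y_true, y_pred)
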