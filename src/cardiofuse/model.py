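"""Scikit-learn-style estimator wrapping the fusion network.

``CrossModalFusionClassifier`` composes with sklearn model selection
(``get_params``/``set_params``/``clone`` work as usual).  Input ``X``
is an (n, 2, L) array with ECG on channel 0 and PCG on channel 1; all
architecture variants accept the same layout, single-modality variants
select their channel internally.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .network import VARIANTS, FusionNetwork, ModelConfig
from .training import TrainConfig, class_weights, fit_network


class CrossModalFusionClassifier(ClassifierMixin, BaseEstimator):
    """Binary cardiac-state classifier from paired ECG/PCG beat segments.

    Parameters mirror the architecture and the training protocol; the
    defaults are the full-scale model (input 2000 samples, channels
    64/128/192/256) and the full training protocol (Adam, lr 0.01
    with x0.1 plateau decay after 5 stalled epochs, early stop after
    20, batch 32, dropout 0.5, inverse-frequency class weights).

    Attributes set by :meth:`fit` carry a trailing underscore:
    ``network_`` (the trained network), ``history_`` (per-epoch loss and
    learning rate plus the stop reason), ``classes_``.
    """

    def __init__(self, variant: str = "full", input_len: int = 2000,
                 channels: tuple[int, ...] = (64, 128, 192, 256),
                 kernel_size: int = 7, se_ratio: int = 16,
                 spatial_reduce: int = 4, spatial_kernel: int = 16,
                 channel_ratio: int = 16,
                 head_hidden: tuple[int, ...] = (128, 64, 32),
                 dropout: float = 0.5, max_epochs: int = 100,
                 learning_rate: float = 0.01, lr_decay_factor: float = 0.1,
                 lr_patience: int = 5, early_stop_patience: int = 20,
                 batch_size: int = 32, eval_batch_size: int = 128,
                 l2: float = 1e-4, loss_tol: float = 0.0,
                 class_weight: str | None = "balanced",
                 epoch_callback=None, random_state: int | None = None):
        self.variant = variant
        self.input_len = input_len
        self.channels = channels
        self.kernel_size = kernel_size
        self.se_ratio = se_ratio
        self.spatial_reduce = spatial_reduce
        self.spatial_kernel = spatial_kernel
        self.channel_ratio = channel_ratio
        self.head_hidden = head_hidden
        self.dropout = dropout
        self.max_epochs = max_epochs
        self.learning_rate = learning_rate
        self.lr_decay_factor = lr_decay_factor
        self.lr_patience = lr_patience
        self.early_stop_patience = early_stop_patience
        self.batch_size = batch_size
        self.eval_batch_size = eval_batch_size
        self.l2 = l2
        self.loss_tol = loss_tol
        self.class_weight = class_weight
        self.epoch_callback = epoch_callback
        self.random_state = random_state

    # -- config assembly ----------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            input_len=self.input_len, channels=tuple(self.channels),
            kernel_size=self.kernel_size, se_ratio=self.se_ratio,
            spatial_reduce=self.spatial_reduce,
            spatial_kernel=self.spatial_kernel,
            channel_ratio=self.channel_ratio,
            head_hidden=tuple(self.head_hidden), dropout=self.dropout,
        )

    def _train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(
            max_epochs=self.max_epochs, learning_rate=self.learning_rate,
            lr_decay_factor=self.lr_decay_factor,
            lr_patience=self.lr_patience,
            early_stop_patience=self.early_stop_patience,
            batch_size=self.batch_size,
            eval_batch_size=self.eval_batch_size, l2=self.l2,
            loss_tol=self.loss_tol, seed=seed,
        )

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[1] != 2 or X.shape[2] != self.input_len:
            raise ValueError(
                f"X must have shape (n, 2, {self.input_len}); got {X.shape}"
            )
        return X

    # -- sklearn API ---------------------------------------------------
    def fit(self, X, y):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        X = self._validate_X(X)
        y = np.asarray(y, dtype=np.int64)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if not np.isin(self.classes_, (0, 1)).all():
            raise ValueError("labels must be 0 (normal) / 1 (abnormal)")
        seed = 0 if self.random_state is None else int(self.random_state)
        counts = np.array([np.sum(y == 0), np.sum(y == 1)])
        if self.class_weight == "balanced" and counts.min() > 0:
            weights = class_weights(counts)
        elif self.class_weight is None or counts.min() == 0:
            weights = None
        else:
            weights = np.asarray(self.class_weight, dtype=np.float64)
        self.network_ = FusionNetwork(self.variant, self._model_config(),
                                      seed=seed)
        self.history_ = fit_network(
            self.network_, X, y, self._train_config(seed), weights,
            epoch_callback=self.epoch_callback,
        )
        self.class_weights_ = weights
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._validate_X(X)
        return self.network_.predict_proba_array(
            X, batch_size=self.eval_batch_size
        )

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(np.int64)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        tags.non_deterministic = False
        return tags
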