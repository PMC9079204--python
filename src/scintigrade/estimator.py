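"""Scikit-learn-style estimator facade over the CNN pipeline.

``PeruginiCNNClassifier`` wraps network construction, pixel-wise z-score
normalisation and the weighted training loop behind the familiar
``fit`` / ``predict`` / ``predict_proba`` interface, so the models compose
with sklearn model selection. Inputs are image stacks of shape
``(n, height, width)``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .models import ModelSpec, build_model
from .preprocess import ZScoreNormalizer
from .training import TrainConfig, compute_class_weights, train_model


class PeruginiCNNClassifier(ClassifierMixin, BaseEstimator):
    """Compact CNN classifier for cardiac-uptake grading.

    Parameters mirror the training recipe defaults (50 epochs, batch 128,
    Adam at 1e-4 with plateau reduction, 10% validation split,
    inverse-frequency class weights). ``architecture`` selects the model
    family; ``stem_filters``/``block_filters`` set the filter plan.

    Attributes set by ``fit`` carry the trailing underscore convention:
    ``classes_``, ``network_``, ``normalizer_``, ``history_``.
    """

    def __init__(self, architecture="linear", stem_filters=16,
                 block_filters=(16, 32, 64, 128), dropout=0.2, pool_stride=2,
                 epochs=50, batch_size=128, learning_rate=1e-4, min_lr=1e-7,
                 lr_patience=2, lr_factor=0.1, validation_fraction=0.1,
                 class_weighting="inverse_frequency", normalize=True,
                 scaled_init=False, head_init_steps=0,
                 average_tail_fraction=0.0, snapshot_ensemble=0,
                 random_state=0):
        self.architecture = architecture
        self.stem_filters = stem_filters
        self.block_filters = block_filters
        self.dropout = dropout
        self.pool_stride = pool_stride
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.min_lr = min_lr
        self.lr_patience = lr_patience
        self.lr_factor = lr_factor
        self.validation_fraction = validation_fraction
        self.class_weighting = class_weighting
        self.normalize = normalize
        self.scaled_init = scaled_init
        self.head_init_steps = head_init_steps
        self.average_tail_fraction = average_tail_fraction
        self.snapshot_ensemble = snapshot_ensemble
        self.random_state = random_state

    def _validate_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError(f"expected (n, height, width) images, got {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("images contain non-finite values")
        return X

    def fit(self, X, y):
        X = self._validate_images(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) not in (2, 4):
            raise ValueError(
                f"this classifier supports 2 or 4 classes, got {len(self.classes_)}")
        if self.normalize:
            self.normalizer_ = ZScoreNormalizer().fit(X)
            Xn = self.normalizer_.transform(X)
        else:
            self.normalizer_ = None
            Xn = X
        spec = ModelSpec(
            family=self.architecture, n_classes=len(self.classes_),
            input_shape=(X.shape[1], X.shape[2], 1),
            stem_filters=self.stem_filters,
            block_filters=tuple(self.block_filters), dropout=self.dropout,
            pool_stride=self.pool_stride, seed=self.random_state,
        )
        handle = build_model(spec)
        weights = (compute_class_weights(y_idx, n_classes=len(self.classes_))
                   if self.class_weighting == "inverse_frequency" else None)
        cfg = TrainConfig(
            epochs=self.epochs, batch_size=self.batch_size,
            initial_lr=self.learning_rate, min_lr=self.min_lr,
            lr_patience=self.lr_patience, lr_factor=self.lr_factor,
            validation_fraction=self.validation_fraction,
            class_weighting=self.class_weighting, seed=self.random_state,
            scaled_init=self.scaled_init,
            head_init_steps=self.head_init_steps,
            average_tail_fraction=self.average_tail_fraction,
            snapshot_ensemble=self.snapshot_ensemble,
        )
        self.network_, self.history_ = train_model(handle, Xn, y_idx, weights, cfg)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "network_")
        X = self._validate_images(X)
        if self.normalizer_ is not None:
            X = self.normalizer_.transform(X)
        return self.network_.predict_proba(X.astype(np.float32))

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]
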