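"""Scikit-learn-style estimator facade over the segmentation network.

``VesselSegmenter`` wraps network construction, seeded training with the
BCE + Jaccard loss and thresholded inference behind the familiar
fit/predict surface, so it composes with sklearn model selection.  X is a
(S, H, W) uint8 slice stack, y the matching {0,1} mask stack.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .metrics import mean_slice_dice
from .model import ModelConfig
from .train import TrainingConfig, train_on_slices
from . import nn

__all__ = ["VesselSegmenter"]


class VesselSegmenter(BaseEstimator):
    """Per-pixel vessel segmentation of transverse CTA slices.

    Parameters
    ----------
    base_channels, blocks_per_stage :
        Encoder width and residual-block depth; defaults are the reduced
        desk-scale network (the full configuration is
        ``base_channels=64, blocks_per_stage=(3, 4, 6, 3)``).
    epochs, batch_size, learning_rate, loss_weights :
        Optimisation settings (Adam; BCE weight, Jaccard weight).
    validation_fraction :
        Trailing fraction of the training slices held out to select the
        best epoch by validation IOU.
    binarize_threshold :
        Probability cut turning the network output into a binary mask.
    random_state :
        Seeds both initialisation and batch shuffling.

    Attributes
    ----------
    net_ : trained network
    history_ : list of per-epoch dicts (train_loss, val_iou)
    best_val_iou_ : best validation IOU across epochs
    """

    def __init__(
        self,
        base_channels: int = 8,
        blocks_per_stage: tuple = (1, 1, 1, 1),
        epochs: int = 20,
        batch_size: int = 15,
        learning_rate: float = 1e-3,
        loss_weights: tuple = (1.0, 1.0),
        validation_fraction: float = 0.15,
        binarize_threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.base_channels = base_channels
        self.blocks_per_stage = blocks_per_stage
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.loss_weights = loss_weights
        self.validation_fraction = validation_fraction
        self.binarize_threshold = binarize_threshold
        self.random_state = random_state

    def _validate_xy(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("X must be a (n_slices, H, W) stack")
        if y is not None:
            y = np.asarray(y)
            if y.shape != X.shape:
                raise ValueError("y must match X in shape")
            if not np.all(np.isin(np.unique(y), (0, 1))):
                raise ValueError("y must be binary {0, 1}")
        return X, y

    def fit(self, X, y):
        X, y = self._validate_xy(X, y)
        n_val = max(1, int(round(self.validation_fraction * X.shape[0])))
        if n_val >= X.shape[0]:
            raise ValueError("validation_fraction leaves no training slices")
        mc = ModelConfig(
            base_channels=self.base_channels,
            blocks_per_stage=tuple(self.blocks_per_stage),
            seed=self.random_state,
        )
        tc = TrainingConfig(
            batch_size=self.batch_size,
            epochs=self.epochs,
            learning_rate=self.learning_rate,
            loss_weights=tuple(self.loss_weights),
            binarize_threshold=self.binarize_threshold,
            seed=self.random_state,
        )
        self.net_, self.history_ = train_on_slices(
            X[:-n_val], y[:-n_val], X[-n_val:], y[-n_val:], mc, tc
        )
        self.best_val_iou_ = max(h["val_iou"] for h in self.history_)
        self.n_slices_fit_ = X.shape[0]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel vessel probabilities, shape (n_slices, H, W)."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        X, _ = self._validate_xy(X)
        xs = X.astype(np.float32)[:, None] / 255.0
        self.net_.eval()
        out = [
            self.net_(nn.Tensor(xs[i : i + self.batch_size])).data[:, 0]
            for i in range(0, xs.shape[0], self.batch_size)
        ]
        return np.concatenate(out)

    def predict(self, X) -> np.ndarray:
        """Binary {0,1} vessel masks, shape (n_slices, H, W)."""
        return (self.predict_proba(X) > self.binarize_threshold).astype(np.uint8)

    def score(self, X, y) -> float:
        """Mean per-slice Dice against reference masks."""
        X, y = self._validate_xy(X, y)
        return mean_slice_dice(self.predict(X), y)
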