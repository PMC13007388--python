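"""scikit-learn-style estimator facade over the training/inference pipeline.

``StreamlineContextClassifier`` wraps phantom-or-real tractogram training
(:func:`fiberparc.train.train_model`) and whole-tractogram prediction
(:func:`fiberparc.infer.predict_tractogram`) behind the familiar
``fit`` / ``predict`` / ``score`` surface, so it composes with sklearn
model selection and pipelines. Samples are whole tractograms (subjects);
labels are per-streamline cluster ids.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .augment import AugmentConfig
from .evaluate import accuracy as _accuracy
from .infer import predict_tractogram
from .model import ModelConfig
from .tractogram_io import Tractogram
from .train import TrainConfig, train_model

__all__ = ["StreamlineContextClassifier"]


def _normalize_input(X):
    """Return (list_of_tractograms, was_single_subject)."""
    if isinstance(X, Tractogram):
        return [X], True
    X = list(X)
    if X and isinstance(X[0], Tractogram):
        return X, False
    # a bare list of (n, 3) streamline arrays is one subject
    return [Tractogram(streamlines=X)], True


def _attach_labels(subjects, y, single):
    if y is None:
        return subjects
    ys = [y] if single else list(y)
    if len(ys) != len(subjects):
        raise ValueError("need one label array per subject")
    return [
        Tractogram(streamlines=t.streamlines, labels=np.asarray(v),
                   source_meta=dict(t.source_meta))
        for t, v in zip(subjects, ys)
    ]


class StreamlineContextClassifier(BaseEstimator):
    """Per-streamline classifier with global subtractogram context.

    Parameters mirror the architecture and optimization configuration;
    see :class:`fiberparc.model.ModelConfig`,
    :class:`fiberparc.train.TrainConfig`, and
    :class:`fiberparc.augment.AugmentConfig` for semantics and full-scale
    defaults. The estimator defaults are desk-scale (small model, short
    schedule) so it is fittable on a laptop CPU.

    Attributes (after ``fit``)
    --------------------------
    model_ : StreamlineTransformer
        Trained weights (best validation macro-F1 checkpoint).
    history_ : TrainHistory
    classes_ : ndarray
        Sorted cluster ids seen during fit.
    n_parameters_ : int
    """

    def __init__(
        self,
        d_model: int = 64,
        n_layers: int = 2,
        n_heads: int = 1,
        ffn_hidden: int = 128,
        dropout: float = 0.1,
        clf_hidden: int = 128,
        n_points: int = 15,
        lr: float = 8.5e-4,
        weight_decay: float = 1e-3,
        batch_size: int = 2,
        epochs: int = 500,
        context_size: int = 256,
        rot_lr_deg: float = 45.0,
        rot_ap_deg: float = 10.0,
        rot_si_deg: float = 10.0,
        noise_sigma: float = 0.001,
        p_flip: float = 0.5,
        p_hemi: float = 0.3,
        inference_batch: int = 512,
        random_state: int = 0,
    ):
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ffn_hidden = ffn_hidden
        self.dropout = dropout
        self.clf_hidden = clf_hidden
        self.n_points = n_points
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.context_size = context_size
        self.rot_lr_deg = rot_lr_deg
        self.rot_ap_deg = rot_ap_deg
        self.rot_si_deg = rot_si_deg
        self.noise_sigma = noise_sigma
        self.p_flip = p_flip
        self.p_hemi = p_hemi
        self.inference_batch = inference_batch
        self.random_state = random_state

    def _configs(self, n_classes: int):
        model_cfg = ModelConfig(
            d_model=self.d_model, n_layers=self.n_layers, n_heads=self.n_heads,
            ffn_hidden=self.ffn_hidden, dropout=self.dropout,
            clf_hidden=self.clf_hidden, n_classes=n_classes,
            n_points=self.n_points,
        )
        aug = AugmentConfig(
            rot_lr_deg=self.rot_lr_deg, rot_ap_deg=self.rot_ap_deg,
            rot_si_deg=self.rot_si_deg, noise_sigma=self.noise_sigma,
            p_flip=self.p_flip, p_hemi=self.p_hemi,
        )
        train_cfg = TrainConfig(
            lr=self.lr, weight_decay=self.weight_decay,
            batch_size=self.batch_size, epochs=self.epochs,
            context_size=self.context_size, augment=aug,
            seed=self.random_state,
        )
        return model_cfg, train_cfg

    def fit(self, X, y=None):
        """Train on one or more labeled tractograms.

        X : Tractogram or sequence of Tractograms (labels attached), or
            sequence of streamline lists with ``y`` giving per-streamline
            label arrays.
        """
        subjects, single = _normalize_input(X)
        subjects = _attach_labels(subjects, y, single)
        for i, t in enumerate(subjects):
            if t.labels is None:
                raise ValueError(f"subject {i} has no labels")
        self.classes_ = np.unique(np.concatenate([t.labels for t in subjects]))
        n_classes = int(self.classes_.max()) + 1
        model_cfg, train_cfg = self._configs(max(n_classes, 2))
        self.model_, self.history_ = train_model(subjects, model_cfg, train_cfg)
        self.n_parameters_ = self.model_.n_parameters()
        return self

    def predict(self, X) -> np.ndarray:
        """Per-streamline cluster ids for a tractogram (or list of them)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        subjects, single = _normalize_input(X)
        preds = [
            predict_tractogram(self.model_, t, context_size=self.context_size,
                               batch_subtractograms=self.inference_batch,
                               seed=self.random_state)
            for t in subjects
        ]
        return preds[0] if single else preds

    def score(self, X, y) -> float:
        """Streamline-level accuracy."""
        _, single = _normalize_input(X)
        preds = self.predict(X)
        if single:
            return _accuracy(np.asarray(y), preds)
        ys = np.concatenate([np.asarray(v) for v in y])
        ps = np.concatenate(preds)
        return _accuracy(ys, ps)
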