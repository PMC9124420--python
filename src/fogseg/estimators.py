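"""Scikit-learn style estimators wrapping the segmentation networks.

Each estimator consumes a *list* of variable-length displacement-feature
sequences (``[T_i, N, C_in]`` arrays) with aligned per-sample label arrays,
mirroring how sequence models such as hmmlearn handle ragged input.  They
follow the sklearn contract: constructor arguments stored verbatim,
``get_params``/``set_params`` via ``BaseEstimator``, fitted state in
trailing-underscore attributes (``model_``, ``history_``, ``config_``), and
``fit``/``predict``/``predict_proba``/``score``.

Use :func:`fogseg.train.trials_to_xy` to turn :class:`~fogseg.io.MarkerTrial`
objects into ``(X, y)``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .losses import LossConfig
from .nn import BiLSTM, MSGCN, MSTCN, ModelConfig
from .train import train

__all__ = ["MSGCNSegmenter", "MSTCNSegmenter", "STGCNSegmenter",
           "TCNSegmenter", "BiLSTMSegmenter"]


class _SequenceSegmenter(BaseEstimator):
    """Shared fit/predict logic for the framewise segmentation models."""

    def __init__(self, num_stages=5, layers_per_stage=10, filters=64,
                 kernel_size=3, causal=False, num_classes=2,
                 lambda_smooth=0.15, tau=4.0, lr=5e-4, epochs=100,
                 batch_size=16, seed=0):
        self.num_stages = num_stages
        self.layers_per_stage = layers_per_stage
        self.filters = filters
        self.kernel_size = kernel_size
        self.causal = causal
        self.num_classes = num_classes
        self.lambda_smooth = lambda_smooth
        self.tau = tau
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed

    # subclasses build the concrete network
    def _make_model(self, config: ModelConfig):
        raise NotImplementedError

    def _config(self, X) -> ModelConfig:
        first = np.asarray(X[0])
        return ModelConfig(num_stages=self.num_stages,
                           layers_per_stage=self.layers_per_stage,
                           filters=self.filters,
                           kernel_size=self.kernel_size,
                           num_classes=self.num_classes,
                           num_nodes=first.shape[1],
                           input_channels=first.shape[2],
                           causal=self.causal)

    def fit(self, X, y):
        """Train on lists of feature sequences and label sequences."""
        if len(X) != len(y):
            raise ValueError("X and y must have equally many sequences")
        self.config_ = self._config(X)
        self.model_ = self._make_model(self.config_)
        loss_cfg = LossConfig(lambda_smooth=self.lambda_smooth, tau=self.tau)
        self.history_ = train(self.model_, list(X), list(y),
                              loss_config=loss_cfg, lr=self.lr,
                              epochs=self.epochs, batch_size=self.batch_size,
                              seed=self.seed)
        self.classes_ = np.arange(self.num_classes)
        return self

    def predict(self, X):
        """Per-sample class labels for each sequence (final-stage argmax)."""
        return [self.model_.predict(np.asarray(x, dtype=np.float32))
                for x in X]

    def predict_proba(self, X):
        """Final-stage per-sample class probabilities for each sequence."""
        return [self.model_.predict_proba(
            np.asarray(x, dtype=np.float32)).probabilities[-1] for x in X]

    def score(self, X, y):
        """Mean framewise accuracy over all samples of all sequences."""
        preds = self.predict(X)
        correct = sum(int(np.sum(p == np.asarray(t)))
                      for p, t in zip(preds, y))
        total = sum(len(t) for t in y)
        return correct / total


class MSGCNSegmenter(_SequenceSegmenter):
    """Multi-stage spatial-temporal graph convolutional segmentation model.

    ``graph=None`` uses the canonical 9-marker lower-limb skeleton; pass a
    :class:`fogseg.graph.SkeletonGraph` for other marker sets.
    """

    def __init__(self, num_stages=5, layers_per_stage=10, filters=64,
                 kernel_size=3, causal=False, num_classes=2,
                 lambda_smooth=0.15, tau=4.0, lr=5e-4, epochs=100,
                 batch_size=16, seed=0, graph=None):
        super().__init__(num_stages, layers_per_stage, filters, kernel_size,
                         causal, num_classes, lambda_smooth, tau, lr, epochs,
                         batch_size, seed)
        self.graph = graph

    def _make_model(self, config):
        return MSGCN(config, graph=self.graph, rng=self.seed)


class STGCNSegmenter(MSGCNSegmenter):
    """Single-stage ST-GCN baseline (MS-GCN without refinement stages)."""

    def _config(self, X):
        cfg = super()._config(X)
        cfg.num_stages = 1
        return cfg


class MSTCNSegmenter(_SequenceSegmenter):
    """Multi-stage TCN baseline on the node-flattened input."""

    def _make_model(self, config):
        return MSTCN(config, rng=self.seed)


class TCNSegmenter(MSTCNSegmenter):
    """Single-stage TCN baseline."""

    def _config(self, X):
        cfg = super()._config(X)
        cfg.num_stages = 1
        return cfg


class BiLSTMSegmenter(_SequenceSegmenter):
    """Bidirectional LSTM sequence labeller (per-sample predictions)."""

    def __init__(self, hidden=64, num_classes=2, lambda_smooth=0.15, tau=4.0,
                 lr=5e-4, epochs=100, batch_size=16, seed=0):
        super().__init__(num_stages=1, layers_per_stage=1, filters=hidden,
                         num_classes=num_classes, lambda_smooth=lambda_smooth,
                         tau=tau, lr=lr, epochs=epochs,
                         batch_size=batch_size, seed=seed)
        self.hidden = hidden

    def get_params(self, deep=True):
        return {"hidden": self.hidden, "num_classes": self.num_classes,
                "lambda_smooth": self.lambda_smooth, "tau": self.tau,
                "lr": self.lr, "epochs": self.epochs,
                "batch_size": self.batch_size, "seed": self.seed}

    def _make_model(self, config):
        return BiLSTM(config, hidden=self.hidden, rng=self.seed)
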