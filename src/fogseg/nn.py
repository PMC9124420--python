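"""Multi-stage spatial-temporal graph convolutional networks and baselines.

The segmentation model maps a displacement-feature sequence ``[T, N, C_in]``
to per-sample class probabilities through ``S`` stages:

* **Prediction-generation stage** — input batch-norm, a 1x1 channel
  adjustment, then a stack of ST-GCN blocks.  Each block applies a
  partitioned spatial graph convolution with a learnable edge mask
  (``f_gcn = sum_p (A_p * M_p) f W_p``), batch-norm + ReLU, a dilated
  acausal temporal convolution (dilation doubling per layer), batch-norm +
  ReLU, and a residual connection from the block input.  A head pools the
  node axis (mean over the N markers), applies a 1x1 convolution and a
  softmax.
* **Refinement stages** — each consumes only the previous stage's softmax
  probabilities (an ``l``-channel sequence), adjusts to ``C`` channels, and
  applies a stack of residual dilated temporal-convolution blocks followed
  by the same 1x1 + softmax head.  Refinements suppress over-segmentation.

Baselines: the multi-stage TCN (graph convolutions replaced by plain
temporal convolutions on the node-flattened ``T x C_in*N`` input), its
single-stage variant, the single-stage ST-GCN, and a bidirectional LSTM
with per-sample heads (plus a sequence-recognition head for the
sliding-window scheme).

All models are fully convolutional in time (the Bi-LSTM is recurrent) and
accept any sequence length with the same weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import SkeletonGraph, default_graph

__all__ = [
    "ModelConfig", "StagewiseOutput", "Module",
    "MSGCN", "MSTCN", "BiLSTM", "BiLSTMRecognizer",
    "build_baseline", "forward_msgcn",
    "input_adjust", "graph_conv", "stage_head",
]


class ConfigurationError(ValueError):
    """Inconsistent model configuration or input shape."""


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: 5 stages (1 prediction
    generation + 4 refinement), 10 layers of 64 filters per stage, kernel
    size 3, dilation doubled each layer (1, 2, 4, ..., 512), acausal.
    """

    num_stages: int = 5
    layers_per_stage: int = 10
    filters: int = 64
    kernel_size: int = 3
    dilation_schedule: tuple = None
    num_classes: int = 2
    num_nodes: int = 9
    input_channels: int = 3
    causal: bool = False

    def __post_init__(self):
        if self.dilation_schedule is None:
            self.dilation_schedule = tuple(2 ** i for i in range(self.layers_per_stage))
        self.dilation_schedule = tuple(int(d) for d in self.dilation_schedule)
        if self.num_stages < 1:
            raise ConfigurationError("num_stages must be >= 1")
        if len(self.dilation_schedule) != self.layers_per_stage:
            raise ConfigurationError(
                "dilation_schedule length must equal layers_per_stage")
        if any(d < 1 for d in self.dilation_schedule):
            raise ConfigurationError("dilations must be positive")
        if not self.causal and self.kernel_size % 2 == 0:
            raise ConfigurationError(
                "acausal convolutions require an odd kernel size")


@dataclass
class StagewiseOutput:
    """Per-stage logits and softmax probabilities, shape [S, T, l]."""

    logits: np.ndarray
    probabilities: np.ndarray

    @property
    def num_stages(self) -> int:
        return len(self.logits)

    def predicted_labels(self) -> np.ndarray:
        """Final prediction: argmax of the last stage's probabilities."""
        return self.probabilities[-1].argmax(axis=-1)


# -- light module system ---------------------------------------------------


class Module:
    """Parameter container with recursive traversal and train/eval modes."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Module):
                    yield item
                    yield from item.modules()

    def named_parameters(self, prefix=""):
        for k, v in self.__dict__.items():
            items = enumerate(v) if isinstance(v, (list, tuple)) else [(None, v)]
            for idx, item in items:
                name = f"{prefix}{k}" if idx is None else f"{prefix}{k}.{idx}"
                if isinstance(item, Tensor) and item.requires_grad:
                    yield name, item
                elif isinstance(item, Module):
                    yield from item.named_parameters(prefix=name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            raise KeyError("state dict does not match model parameters")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data[...] = state[name]


def _uniform(rng, shape, fan_in):
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(np.float32),
                  requires_grad=True)


class Conv1x1(Module):
    """Pointwise (1x1) convolution over the channel axis; no temporal mixing."""

    def __init__(self, c_in, c_out, rng):
        super().__init__()
        self.weight = _uniform(rng, (c_in, c_out), c_in)
        self.bias = _uniform(rng, (c_out,), c_in)

    def forward(self, x):
        return ad.linear(x, self.weight, self.bias)


class BatchNorm(Module):
    """Masked per-channel batch normalization with running statistics."""

    def __init__(self, c, momentum=0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(c, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, np.float32), requires_grad=True)
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self.momentum = momentum

    def forward(self, x, mask=None):
        return ad.batch_norm(x, self.gamma, self.beta, mask=mask,
                             running_mean=self.running_mean,
                             running_var=self.running_var,
                             momentum=self.momentum, training=self.training)


class TemporalConv(Module):
    """Dilated 1-D convolution along time; length-preserving."""

    def __init__(self, c_in, c_out, kernel_size, dilation, causal, rng):
        super().__init__()
        fan_in = c_in * kernel_size
        self.weight = _uniform(rng, (kernel_size, c_in, c_out), fan_in)
        self.bias = _uniform(rng, (c_out,), fan_in)
        self.dilation = int(dilation)
        self.causal = causal

    def forward(self, x):
        return ad.dilated_conv_time(x, self.weight, self.bias,
                                    self.dilation, self.causal)


class GraphConvLayer(Module):
    """Partitioned spatial graph convolution with learnable edge masks.

    ``f_gcn = sum_p (A_p * M_p) f W_p + b``; the masks M_p start at the
    multiplicative identity (all ones).
    """

    def __init__(self, c_in, c_out, partitions: np.ndarray, rng):
        super().__init__()
        P, N, _ = partitions.shape
        self.partitions = partitions.astype(np.float32)
        self.edge_mask = Tensor(np.ones((P, N, N), np.float32), requires_grad=True)
        self.weight = _uniform(rng, (P, c_in, c_out), c_in * P)
        self.bias = _uniform(rng, (c_out,), c_in * P)

    def forward(self, x):
        return ad.graph_conv(x, self.partitions, self.edge_mask,
                             self.weight, self.bias)


class STGCNBlock(Module):
    """Graph conv -> BN -> ReLU -> dilated temporal conv -> BN -> ReLU -> +residual."""

    def __init__(self, c, kernel_size, dilation, partitions, causal, rng):
        super().__init__()
        self.gcn = GraphConvLayer(c, c, partitions, rng)
        self.bn1 = BatchNorm(c)
        self.tcn = TemporalConv(c, c, kernel_size, dilation, causal, rng)
        self.bn2 = BatchNorm(c)

    def forward(self, x, mask=None):
        h = ad.relu(self.bn1.forward(self.gcn.forward(x), mask))
        h = ad.relu(self.bn2.forward(self.tcn.forward(h), mask))
        return ad.add(h, x)


class TCNBlock(Module):
    """Dilated temporal conv -> BN -> ReLU -> +residual."""

    def __init__(self, c, kernel_size, dilation, causal, rng):
        super().__init__()
        self.tcn = TemporalConv(c, c, kernel_size, dilation, causal, rng)
        self.bn = BatchNorm(c)

    def forward(self, x, mask=None):
        h = ad.relu(self.bn.forward(self.tcn.forward(x), mask))
        return ad.add(h, x)


class StageHead(Module):
    """Mean-pool the node axis, 1x1 conv to l classes, softmax."""

    def __init__(self, c, num_classes, rng):
        super().__init__()
        self.out = Conv1x1(c, num_classes, rng)

    def forward(self, x):
        pooled = ad.tmean(x, axis=2, keepdims=True)   # [B,T,1,C]
        logits = self.out.forward(pooled)
        return logits, ad.softmax(logits, axis=-1)


class RefinementStage(Module):
    """TCN stage re-predicting from the previous stage's probabilities only."""

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        self.adjust = Conv1x1(config.num_classes, config.filters, rng)
        self.blocks = [
            TCNBlock(config.filters, config.kernel_size, d, config.causal, rng)
            for d in config.dilation_schedule
        ]
        self.head = StageHead(config.filters, config.num_classes, rng)

    def forward(self, probs, mask=None, mask_t=None):
        h = self.adjust.forward(probs)                 # [B,T,1,C]
        for blk in self.blocks:
            h = blk.forward(h, mask)
            if mask_t is not None:
                h = ad.mul(h, mask_t)
        return self.head.forward(h)


class _MultiStageBase(Module):
    """Shared stage-stacking logic for MS-GCN and MS-TCN."""

    def forward(self, x, mask=None):
        """``x [B, T, N, C_in]`` (or [T, N, C_in]); returns list of
        (logits, probabilities) Tensor pairs, one per stage, each [B, T, 1, l]."""
        x = ad.astensor(x)
        if x.ndim == 3:
            x = ad.reshape(x, (1,) + x.shape)
        mask_t = None
        if mask is not None:
            mask_t = Tensor(np.asarray(mask, dtype=x.data.dtype)[:, :, None, None])
        outputs = [self._first_stage(x, mask, mask_t)]
        for stage in self.refinements:
            outputs.append(stage.forward(outputs[-1][1], mask, mask_t))
        return outputs

    def predict_proba(self, features) -> StagewiseOutput:
        """Run a single sequence in eval mode; returns stacked [S, T, l] arrays."""
        was_training = self.training
        self.eval()
        try:
            with ad.no_grad():
                outputs = self.forward(features)
        finally:
            if was_training:
                self.train()
        logits = np.stack([lo.data[0, :, 0] for lo, _ in outputs])
        probs = np.stack([pr.data[0, :, 0] for _, pr in outputs])
        return StagewiseOutput(logits=logits, probabilities=probs)

    def predict(self, features) -> np.ndarray:
        return self.predict_proba(features).predicted_labels()


class MSGCN(_MultiStageBase):
    """Multi-stage spatial-temporal graph convolutional network."""

    def __init__(self, config: ModelConfig = None, graph: SkeletonGraph = None,
                 rng=None):
        super().__init__()
        self.config = config = config or ModelConfig()
        graph = graph or default_graph()
        if graph.num_nodes != config.num_nodes:
            raise ConfigurationError(
                f"graph has {graph.num_nodes} nodes, config expects {config.num_nodes}")
        parts = graph.partitions
        if parts.shape[0] != 3:
            raise ConfigurationError("expected P=3 partitioned adjacency")
        rng = np.random.default_rng(rng)
        self.input_bn = BatchNorm(config.input_channels)
        self.adjust = Conv1x1(config.input_channels, config.filters, rng)
        self.blocks = [
            STGCNBlock(config.filters, config.kernel_size, d, parts,
                       config.causal, rng)
            for d in config.dilation_schedule
        ]
        self.head = StageHead(config.filters, config.num_classes, rng)
        self.refinements = [RefinementStage(config, rng)
                            for _ in range(config.num_stages - 1)]

    def _first_stage(self, x, mask, mask_t):
        if x.shape[2] != self.config.num_nodes:
            raise ConfigurationError(
                f"input has {x.shape[2]} nodes, config expects {self.config.num_nodes}")
        h = self.input_bn.forward(x, mask)
        h = self.adjust.forward(h)
        for blk in self.blocks:
            h = blk.forward(h, mask)
            if mask_t is not None:
                h = ad.mul(h, mask_t)
        return self.head.forward(h)


class MSTCN(_MultiStageBase):
    """Multi-stage TCN on the node-flattened input (T x C_in*N)."""

    def __init__(self, config: ModelConfig = None, rng=None):
        super().__init__()
        self.config = config = config or ModelConfig()
        rng = np.random.default_rng(rng)
        c_in = config.input_channels * config.num_nodes
        self.input_bn = BatchNorm(c_in)
        self.adjust = Conv1x1(c_in, config.filters, rng)
        self.blocks = [
            TCNBlock(config.filters, config.kernel_size, d, config.causal, rng)
            for d in config.dilation_schedule
        ]
        self.head = StageHead(config.filters, config.num_classes, rng)
        self.refinements = [RefinementStage(config, rng)
                            for _ in range(config.num_stages - 1)]

    def _first_stage(self, x, mask, mask_t):
        B, T = x.shape[:2]
        flat = ad.reshape(x, (B, T, 1, x.shape[2] * x.shape[3]))
        h = self.input_bn.forward(flat, mask)
        h = self.adjust.forward(h)
        for blk in self.blocks:
            h = blk.forward(h, mask)
            if mask_t is not None:
                h = ad.mul(h, mask_t)
        return self.head.forward(h)


class BiLSTM(Module):
    """Bidirectional LSTM sequence labeller: two forward and two backward
    64-cell layers, concatenated per sample, with a linear softmax head."""

    def __init__(self, config: ModelConfig = None, hidden: int = 64, rng=None):
        super().__init__()
        self.config = config = config or ModelConfig()
        rng = np.random.default_rng(rng)
        c_in = config.input_channels * config.num_nodes
        self.hidden = hidden

        def make(cin):
            return {
                "w_ih": _uniform(rng, (cin, 4 * hidden), cin),
                "w_hh": _uniform(rng, (hidden, 4 * hidden), hidden),
                "b": _uniform(rng, (4 * hidden,), hidden),
            }

        self.fwd1, self.bwd1 = _LSTMCellParams(make(c_in)), _LSTMCellParams(make(c_in))
        self.fwd2 = _LSTMCellParams(make(2 * hidden))
        self.bwd2 = _LSTMCellParams(make(2 * hidden))
        self.head = Conv1x1(2 * hidden, config.num_classes, rng)

    def _encode(self, x):
        """x [B, T, C] -> hidden sequence [B, T, 2H]."""
        h1 = ad.concat([self.fwd1.run(x, False), self.bwd1.run(x, True)], axis=-1)
        h2 = ad.concat([self.fwd2.run(h1, False), self.bwd2.run(h1, True)], axis=-1)
        return h2

    def forward(self, x, mask=None):
        x = ad.astensor(x)
        if x.ndim == 3:
            x = ad.reshape(x, (1,) + x.shape)
        B, T = x.shape[:2]
        flat = ad.reshape(x, (B, T, x.shape[2] * x.shape[3]))
        h = self._encode(flat)
        logits = ad.reshape(self.head.forward(h), (B, T, 1, -1))
        return [(logits, ad.softmax(logits, axis=-1))]

    def predict_proba(self, features) -> StagewiseOutput:
        with ad.no_grad():
            outputs = self.forward(features)
        logits = np.stack([lo.data[0, :, 0] for lo, _ in outputs])
        probs = np.stack([pr.data[0, :, 0] for _, pr in outputs])
        return StagewiseOutput(logits=logits, probabilities=probs)

    def predict(self, features) -> np.ndarray:
        return self.predict_proba(features).predicted_labels()


class _LSTMCellParams(Module):
    def __init__(self, params: dict):
        super().__init__()
        self.w_ih = params["w_ih"]
        self.w_hh = params["w_hh"]
        self.b = params["b"]

    def run(self, x, reverse: bool):
        return ad.lstm(x, self.w_ih, self.w_hh, self.b, reverse=reverse)


class BiLSTMRecognizer(BiLSTM):
    """Sequence-level recognizer for the sliding-window scheme.

    Encodes a fixed window and feeds the final hidden state (last step of
    the forward direction, first step of the backward direction) through a
    feed-forward head to one label per window.
    """

    def forward(self, x, mask=None):
        x = ad.astensor(x)
        if x.ndim == 3:
            x = ad.reshape(x, (1,) + x.shape)
        B, T = x.shape[:2]
        flat = ad.reshape(x, (B, T, x.shape[2] * x.shape[3]))
        h = self._encode(flat)                        # [B, T, 2H]
        last = h[:, T - 1, : self.hidden]
        first = h[:, 0, self.hidden:]
        summary = ad.concat([last, first], axis=-1)   # [B, 2H]
        logits = self.head.forward(summary)           # [B, l]
        return logits, ad.softmax(logits, axis=-1)

    def predict_windows(self, windows) -> np.ndarray:
        """Predict one label per window; ``windows [B, W, N, C]``."""
        with ad.no_grad():
            _, probs = self.forward(windows)
        return probs.data.argmax(axis=-1)


def build_baseline(kind: str, config: ModelConfig = None, rng=None) -> Module:
    """Construct a baseline model: 'stgcn', 'mstcn', 'tcn' or 'bilstm'.

    'stgcn' and 'tcn' are the single-stage variants of MS-GCN and MS-TCN
    (same configuration, no refinement stages).
    """
    config = config or ModelConfig()
    kind = kind.lower()
    if kind == "mstcn":
        return MSTCN(config, rng=rng)
    if kind == "tcn":
        cfg = ModelConfig(**{**config.__dict__, "num_stages": 1})
        return MSTCN(cfg, rng=rng)
    if kind == "stgcn":
        cfg = ModelConfig(**{**config.__dict__, "num_stages": 1})
        return MSGCN(cfg, rng=rng)
    if kind == "bilstm":
        return BiLSTM(config, rng=rng)
    raise ConfigurationError(f"unknown baseline kind {kind!r}")


# -- thin functional wrappers ----------------------------------------------


def input_adjust(features, weight, bias=None):
    """Pointwise channel adjustment ``W1 * f_in + b`` (no temporal mixing)."""
    y = ad.linear(ad.astensor(features), ad.astensor(weight),
                  ad.astensor(bias) if bias is not None else None)
    return y.data


def graph_conv(features, partitions, weights, masks=None, bias=None):
    """Functional partitioned graph convolution over [T, N, C] features."""
    x = np.asarray(features)
    single = x.ndim == 3
    if single:
        x = x[None]
    P = np.asarray(partitions)
    M = np.ones_like(P) if masks is None else np.asarray(masks)
    b = np.zeros(np.asarray(weights).shape[-1]) if bias is None else bias
    y = ad.graph_conv(Tensor(x), P, Tensor(M), Tensor(np.asarray(weights)),
                      Tensor(np.asarray(b))).data
    return y[0] if single else y


def stage_head(features, weight=None, bias=None):
    """Mean-pool nodes then 1x1 + softmax; accepts [T, N, C] or [T, C]."""
    x = np.asarray(features, dtype=np.float32)
    if x.ndim == 3:
        x = x.mean(axis=1)
    if weight is not None:
        x = x @ np.asarray(weight) + (0 if bias is None else np.asarray(bias))
    probs = ad.softmax(Tensor(x), axis=-1).data
    return x, probs


def forward_msgcn(features, config: ModelConfig = None,
                  model: MSGCN = None, rng=None) -> StagewiseOutput:
    """Run MS-GCN over one feature sequence ``[T, N, C_in]``."""
    if model is None:
        model = MSGCN(config or ModelConfig(), rng=rng)
    return model.predict_proba(np.asarray(features, dtype=np.float32))
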