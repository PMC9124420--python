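"""Training objective: cross-entropy plus truncated smoothing loss, per stage.

The per-stage loss is ``L = L_cls + lambda * L_T-MSE`` where ``L_cls`` is the
mean negative log-probability of the true class and ``L_T-MSE`` is a
truncated mean squared error of the sample-wise log-probability differences

    Delta_{t,c} = |log p_{t,c} - log p_{t-1,c}|,   Delta~ = min(Delta, tau),

averaged over the valid transitions and classes, with the ``t-1`` term
treated as a constant during differentiation (gradient stopping, as in the
multi-stage TCN training objective).  The truncation caps each summand at
``tau**2``, so the smoothing loss itself never exceeds ``tau**2``.  The total
training loss is the sum of the per-stage losses over all stages, each stage
scored on its own softmax probabilities.

Defaults: ``lambda = 0.15``, ``tau = 4``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["LossConfig", "cls_loss", "smoothing_loss", "total_loss",
           "LabelError"]

_EPS = 1e-8


class LabelError(ValueError):
    """A label index is outside the configured class range."""


@dataclass
class LossConfig:
    lambda_smooth: float = 0.15
    tau: float = 4.0
    class_weights: tuple | None = None

    def __post_init__(self):
        if self.lambda_smooth < 0:
            raise ValueError("lambda_smooth must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


def _prepare(probs, labels, mask):
    probs = ad.astensor(probs)
    if probs.ndim == 4:                      # [B, T, 1, l] stage output
        probs = ad.reshape(probs, (probs.shape[0], probs.shape[1], probs.shape[3]))
    elif probs.ndim == 2:                    # [T, l]
        probs = ad.reshape(probs, (1,) + probs.shape)
    labels = None if labels is None else np.atleast_2d(np.asarray(labels))
    if mask is not None:
        mask = np.atleast_2d(np.asarray(mask)).astype(probs.data.dtype)
    return probs, labels, mask


def cls_loss(probabilities, labels, mask=None,
             class_weights=None) -> Tensor:
    """Mean cross-entropy over valid samples.

    ``probabilities`` is ``[T, l]`` (or batched ``[B, T, l]`` /
    ``[B, T, 1, l]``); ``labels`` the integer true classes; ``mask`` marks
    valid (non-padding) samples.  Probabilities are clamped at 1e-8 before
    the log.
    """
    probs, labels, mask = _prepare(probabilities, labels, mask)
    B, T, L = probs.shape
    if labels.shape != (B, T):
        raise ValueError(f"labels shape {labels.shape} != {(B, T)}")
    if labels.min() < 0 or labels.max() >= L:
        raise LabelError(f"labels must lie in [0, {L})")
    onehot = np.zeros((B, T, L), dtype=probs.data.dtype)
    np.put_along_axis(onehot, labels[:, :, None], 1.0, axis=2)
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=probs.data.dtype)
        onehot = onehot * w[labels][:, :, None]
    logp = ad.log(ad.clip_min(probs, _EPS))
    nll = ad.mul(ad.mul(logp, onehot), -1.0)         # [B,T,L]
    per_sample = ad.tsum(nll, axis=2)                # [B,T]
    if mask is None:
        return ad.tmean(per_sample)
    total = ad.tsum(ad.mul(per_sample, mask))
    return ad.mul(total, 1.0 / float(mask.sum()))


def smoothing_loss(probabilities, mask=None, tau: float = 4.0) -> Tensor:
    """Truncated MSE of consecutive log-probability differences.

    Averaged over valid transitions and classes; each squared, truncated
    difference is capped at ``tau**2``.  The previous-sample log-probability
    is detached (no gradient flows through it).
    """
    probs, _, mask = _prepare(probabilities, None, mask)
    B, T, L = probs.shape
    if T < 2:
        raise ValueError("smoothing loss needs at least 2 samples")
    logp = ad.log(ad.clip_min(probs, _EPS))
    cur = logp[:, 1:]
    prev = logp[:, :-1].detach()
    delta = ad.tabs(ad.add(cur, ad.mul(prev, -1.0)))
    trunc = ad.minimum(delta, float(tau))
    sq = ad.square(trunc)                            # [B, T-1, L]
    if mask is None:
        return ad.tmean(sq)
    tmask = (mask[:, 1:] * mask[:, :-1])             # both ends valid
    total = ad.tsum(ad.mul(sq, tmask[:, :, None]))
    return ad.mul(total, 1.0 / float(tmask.sum() * L))


def total_loss(stagewise, labels, config: LossConfig = None,
               mask=None) -> Tensor:
    """Sum over stages of ``cls + lambda * smoothing``.

    ``stagewise`` is a list of per-stage probability tensors (the training
    forward pass) or a :class:`fogseg.nn.StagewiseOutput`.
    """
    config = config or LossConfig()
    if hasattr(stagewise, "probabilities") and not isinstance(stagewise, (list, tuple)):
        stages = [stagewise.probabilities[s]
                  for s in range(stagewise.num_stages)]
    else:
        stages = list(stagewise)
    loss = None
    for stage_probs in stages:
        if isinstance(stage_probs, tuple):           # (logits, probs) pair
            stage_probs = stage_probs[1]
        term = cls_loss(stage_probs, labels, mask,
                        class_weights=config.class_weights)
        if config.lambda_smooth > 0:
            sm = smoothing_loss(stage_probs, mask, tau=config.tau)
            term = ad.add(term, ad.mul(sm, config.lambda_smooth))
        loss = term if loss is None else ad.add(loss, term)
    return loss
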