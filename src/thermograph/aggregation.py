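"""Self-attention pooling, sequence-structure fusion and prediction heads.

Variable-length proteins are reduced to fixed-size vectors by grouped
self-attention pooling.  For a representation H (L x D) the attention matrix

    A_g = softmax(W2 tanh(W1 H^T))        (D'' x L)

holds D'' independent groups of attention weights, each softmax-normalised
over the residue axis (masked positions receive exactly zero weight).  The
pooled vector averages the group summaries:

    G_tilde = A_g H  (D'' x D),   h_tilde = mean over the D'' rows.

Each branch (structure G, sequence X) is pooled with its own parameters; the
two pooled vectors are concatenated and a fully connected layer produces the
class logits or the melting-temperature estimate.  The training objective is
cross-entropy (classification) or RMSE (regression) plus ``alpha`` times the
contrastive loss.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "AttentionParams",
    "HeadParams",
    "LossConfig",
    "init_attention",
    "init_head",
    "attention_weights",
    "pool",
    "fuse_and_predict",
    "prediction_loss",
    "total_loss",
]

_MASK_LOGIT = -1e30  # effectively -inf; keeps the softmax finite


@dataclasses.dataclass
class AttentionParams:
    """The two learnable matrices of one pooling head: W1 (D_a x D), W2 (D'' x D_a)."""

    W1: np.ndarray
    W2: np.ndarray

    def __post_init__(self):
        w1 = self.W1.data if isinstance(self.W1, Tensor) else self.W1
        w2 = self.W2.data if isinstance(self.W2, Tensor) else self.W2
        if w2.shape[1] != w1.shape[0]:
            raise ValueError("W2 columns must match W1 rows (attention dim D_a)")


@dataclasses.dataclass
class HeadParams:
    """Fully connected fusion head: weight (2D x out), bias (out,)."""

    weight: np.ndarray
    bias: np.ndarray


@dataclasses.dataclass
class LossConfig:
    """Task and contrastive weight alpha of the overall loss."""

    task: str = "classification"
    alpha: float = 0.1

    def __post_init__(self):
        if self.task not in ("classification", "regression"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


def init_attention(
    D: int, rng: np.random.Generator, D_a: int | None = None, n_groups: int = 4
) -> AttentionParams:
    """Xavier-initialised pooling parameters; D_a defaults to D."""
    D_a = D if D_a is None else D_a
    return AttentionParams(
        W1=rng.standard_normal((D_a, D)) / np.sqrt(D),
        W2=rng.standard_normal((n_groups, D_a)) / np.sqrt(D_a),
    )


def init_head(D: int, out_dim: int, rng: np.random.Generator) -> HeadParams:
    return HeadParams(
        weight=rng.standard_normal((2 * D, out_dim)) / np.sqrt(2 * D),
        bias=np.zeros(out_dim),
    )


def _t(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def attention_weights(H, params: AttentionParams, mask=None):
    """Grouped attention weights A_g (D'' x L) over the residue axis.

    ``mask`` marks valid residues; masked positions get exactly zero weight
    and each group row sums to 1 over the valid positions.  An all-masked
    input is an error.  Returns the kind of its input (ndarray or Tensor).
    """
    is_tensor = isinstance(H, Tensor)
    h = _t(H)
    L = h.shape[0]
    if mask is None:
        mask = np.ones(L, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (L,):
        raise ValueError(f"mask length {mask.shape} does not match L={L}")
    if not mask.any():
        raise ValueError("attention over an all-masked (empty) protein")
    logits = _t(params.W2) @ ad.tanh(_t(params.W1) @ h.T)  # (D'', L)
    bias = np.where(mask, 0.0, _MASK_LOGIT)
    a = ad.softmax(logits + Tensor(bias[None, :]), axis=1)
    # clamp the ~1e-30 leakage at padded positions to exactly zero
    a = a * Tensor(mask[None, :].astype(np.float64))
    return a if is_tensor else a.data


def pool(H, A_g):
    """h_tilde = mean over the D'' rows of A_g @ H; a (D,) protein vector."""
    h, a = _t(H), _t(A_g)
    if a.shape[1] != h.shape[0]:
        raise ValueError("attention width does not match residue count")
    pooled = (a @ h).mean(axis=0)
    return pooled if isinstance(H, Tensor) or isinstance(A_g, Tensor) else pooled.data


def fuse_and_predict(g_tilde, x_tilde, params: HeadParams):
    """[g_tilde || x_tilde] W + b -> class logits (C,) or t_m estimate (1,)."""
    g, x = _t(g_tilde), _t(x_tilde)
    w, b = _t(params.weight), _t(params.bias)
    fused = ad.concatenate([g, x], axis=0)
    if fused.shape[0] != w.shape[0]:
        raise ValueError(
            f"fused dim {fused.shape[0]} does not match head input {w.shape[0]}"
        )
    out = fused @ w + b
    return (
        out
        if isinstance(g_tilde, Tensor) or isinstance(x_tilde, Tensor)
        else out.data
    )


def prediction_loss(outputs, targets, task: str):
    """Mean cross-entropy over softmaxed logits, or batch RMSE.

    ``outputs`` is (B, C) logits for classification or (B,) / (B, 1)
    estimates for regression; ``targets`` is (B,) class indices or
    temperatures.  Returns the kind of ``outputs``.
    """
    is_tensor = isinstance(outputs, Tensor)
    out = _t(outputs)
    targets = np.asarray(targets)
    if targets.size == 0:
        raise ValueError("prediction_loss on an empty batch")
    if task == "classification":
        idx = targets.astype(np.int64)
        C = out.shape[1]
        if idx.min() < 0 or idx.max() >= C:
            raise ValueError(f"class index out of range for C={C}")
        logp = ad.log_softmax(out, axis=1)
        onehot = np.zeros(out.shape)
        onehot[np.arange(len(idx)), idx] = 1.0
        loss = -(logp * Tensor(onehot)).sum() * (1.0 / len(idx))
    elif task == "regression":
        pred = out if out.ndim == 1 else out.sum(axis=1)  # (B, 1) -> (B,)
        err = pred - Tensor(targets.astype(np.float64))
        mse = (err * err).mean()
        # the tiny shift keeps d(sqrt)/d(mse) finite at a perfect fit
        loss = (mse + 1e-30) ** 0.5 if is_tensor else mse ** 0.5
    else:
        raise ValueError(f"unknown task {task!r}")
    return loss if is_tensor else loss.item()


def total_loss(pred_loss, cont_loss, cfg: LossConfig):
    """Overall objective: prediction loss plus alpha times the contrastive loss."""
    if isinstance(pred_loss, Tensor) or isinstance(cont_loss, Tensor):
        return _t(pred_loss) + _t(cont_loss) * cfg.alpha
    return float(pred_loss) + cfg.alpha * float(cont_loss)
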