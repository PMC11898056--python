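"""Residue-type-guided contrastive learning between sequence and structure.

The two encoder branches yield per-residue representations X (sequence) and
G (structure).  A triplet scheme ties them together:

* sample L_s residues; the sampled sequence rows X_s are the *anchors* and
  the same residues' structure rows G_s the *positives*;
* for each anchor, sample K *negatives* from the sampled anchors whose
  amino-acid type differs from the anchor's;
* positive similarity: Psi[i, j] = omega * cos(x_i, g_j) with 0 < omega < 1,
  and the positive loss pulls the diagonal up,
      L_pos = -(1/L_s) sum_i log sigmoid(Psi[i, i]);
* the negative loss pushes anchor/negative pairs apart,
      L_neg = -(1/M) sum_{i,k} log sigmoid(-omega * cos(x_i, x_{n(i,k)}));
* the contrastive loss is L_cont = L_pos + L_neg.

Residues of unknown amino-acid type join neither role.  Functions accept
numpy arrays or autodiff Tensors, so the same code path serves analysis and
training.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import UNKNOWN_RESIDUE

__all__ = [
    "ContrastiveConfig",
    "ContrastiveSample",
    "sample_residues",
    "build_negative_sets",
    "pairwise_similarity",
    "positive_loss",
    "negative_loss",
    "contrastive_loss",
]

_NORM_EPS = 1e-12  # guards cosine against zero rows (e.g. fully ReLU-dead)


@dataclasses.dataclass
class ContrastiveConfig:
    """Sampling and scaling knobs of the contrastive scheme."""

    L_s: int = 64  # residues sampled per protein
    K: int = 5  # negatives per anchor
    omega: float = 0.5  # similarity scale factor, 0 < omega < 1
    enabled: bool = True
    kernel: str = "cosine"  # "cosine" | "dot"

    def __post_init__(self):
        if self.L_s < 1 or self.K < 1:
            raise ValueError("L_s and K must be >= 1")
        if not 0.0 < self.omega < 1.0:
            raise ValueError("omega must lie strictly in (0, 1)")
        if self.kernel not in ("cosine", "dot"):
            raise ValueError(f"unknown similarity kernel {self.kernel!r}")


@dataclasses.dataclass
class ContrastiveSample:
    """Sampled residues with anchor/positive rows and per-anchor negatives."""

    indices: np.ndarray  # sampled residue positions in the protein
    X_s: object  # (L_s, D) anchor rows (ndarray or Tensor)
    G_s: object  # (L_s, D) positive rows
    labels: np.ndarray  # residue type codes of the sample
    negatives: list | None = None  # per anchor: array of indices into the sample


def sample_residues(X, G, labels, cfg: ContrastiveConfig, rng: np.random.Generator):
    """Uniform sample (without replacement) of residues eligible for contrast.

    Only residues with a known amino-acid type are eligible; if none are, all
    positions are used (negatives will then be empty).  Undersized proteins
    contribute all eligible positions in original order.
    """
    labels = np.asarray(labels)
    n_x = X.shape[0]
    if n_x != G.shape[0] or n_x != len(labels):
        raise ValueError(
            f"X ({X.shape}), G ({G.shape}) and labels ({len(labels)}) disagree on L"
        )
    eligible = np.flatnonzero(labels != UNKNOWN_RESIDUE)
    if eligible.size == 0:
        eligible = np.arange(n_x)
    if eligible.size <= cfg.L_s:
        idx = eligible
    else:
        idx = np.sort(rng.choice(eligible, size=cfg.L_s, replace=False))
    rows = (lambda m: m.rows(idx)) if isinstance(X, Tensor) else (lambda m: m[idx])
    return ContrastiveSample(
        indices=idx, X_s=rows(X), G_s=rows(G), labels=labels[idx]
    )


def build_negative_sets(
    sample: ContrastiveSample, K: int, rng: np.random.Generator
) -> ContrastiveSample:
    """Fill per-anchor negative index sets.

    For anchor i the candidates are sampled positions j with a different,
    known residue type.  K draws are uniform without replacement when there
    are at least K candidates, with replacement when there are fewer, and the
    set is empty (anchor skipped in the negative loss) when there are none.
    """
    labels = sample.labels
    negatives = []
    for i in range(len(labels)):
        cand = np.flatnonzero(
            (labels != labels[i]) & (labels != UNKNOWN_RESIDUE)
        )
        if labels[i] == UNKNOWN_RESIDUE or cand.size == 0:
            negatives.append(np.empty(0, dtype=np.int64))
        elif cand.size >= K:
            negatives.append(rng.choice(cand, size=K, replace=False))
        else:
            negatives.append(rng.choice(cand, size=K, replace=True))
    sample.negatives = negatives
    return sample


def _normalized_rows(M, kernel: str):
    """Rows scaled to unit norm (cosine kernel) or left as-is (dot kernel)."""
    if kernel == "dot":
        return M
    if isinstance(M, Tensor):
        norms = ((M * M).sum(axis=1, keepdims=True) + _NORM_EPS) ** 0.5
        return M / norms
    norms = np.sqrt((M * M).sum(axis=1, keepdims=True) + _NORM_EPS)
    return M / norms


def pairwise_similarity(X_s, G_s, omega: float, kernel: str = "cosine"):
    """Psi[i, j] = omega * cos(x_i, g_j) (all anchor/positive pairs).

    Rows of exactly zero norm get similarity 0 by convention.  Returns the
    same kind (ndarray or Tensor) as its inputs.
    """
    xn = _normalized_rows(X_s, kernel)
    gn = _normalized_rows(G_s, kernel)
    psi = (xn @ gn.T) * omega
    return psi


def positive_loss(psi):
    """L_pos = -(1/L_s) sum_i log sigmoid(Psi[i, i]) = mean softplus(-Psi_ii)."""
    if isinstance(psi, Tensor):
        if psi.shape[0] != psi.shape[1]:
            raise ValueError("Psi must be square")
        diag = psi.rows(np.arange(psi.shape[0])) * Tensor(np.eye(psi.shape[0]))
        diag = diag.sum(axis=1)
        return ad.softplus(-diag).mean()
    psi = np.asarray(psi, dtype=np.float64)
    if psi.ndim != 2 or psi.shape[0] != psi.shape[1]:
        raise ValueError("Psi must be square")
    return float(np.mean(np.logaddexp(0.0, -np.diag(psi))))


def negative_loss(sample: ContrastiveSample, omega: float, kernel: str = "cosine"):
    """L_neg = -(1/M) sum log sigmoid(-omega cos(x_i, x_neg)); 0 when M = 0."""
    if sample.negatives is None:
        raise ValueError("negative sets not built; call build_negative_sets first")
    anchors = [i for i, neg in enumerate(sample.negatives) if neg.size > 0]
    if not anchors:
        return Tensor(0.0) if isinstance(sample.X_s, Tensor) else 0.0
    if isinstance(sample.X_s, Tensor):
        xn = _normalized_rows(sample.X_s, kernel)
        terms = []
        for i in anchors:
            a = xn.rows(np.full(len(sample.negatives[i]), i))
            n = xn.rows(sample.negatives[i])
            cos = (a * n).sum(axis=1)
            terms.append(ad.softplus(cos * omega))
        return ad.concatenate(terms).mean()
    xn = _normalized_rows(np.asarray(sample.X_s, dtype=np.float64), kernel)
    total, count = 0.0, 0
    for i in anchors:
        for j in sample.negatives[i]:
            cos = float(xn[i] @ xn[j])
            total += np.logaddexp(0.0, omega * cos)
            count += 1
    return total / count


def contrastive_loss(X, G, labels, cfg: ContrastiveConfig, rng: np.random.Generator):
    """Full contrastive loss on one fresh sample: L_pos + L_neg.

    Returns 0 when the scheme is disabled.  Accepts Tensors (training) or
    numpy arrays (analysis).
    """
    if not cfg.enabled:
        return Tensor(0.0) if isinstance(X, Tensor) else 0.0
    sample = sample_residues(X, G, labels, cfg, rng)
    sample = build_negative_sets(sample, cfg.K, rng)
    psi = pairwise_similarity(sample.X_s, sample.G_s, cfg.omega, cfg.kernel)
    l_pos = positive_loss(psi)
    l_neg = negative_loss(sample, cfg.omega, cfg.kernel)
    return l_pos + l_neg
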