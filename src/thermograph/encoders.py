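"""Sequence and structure encoders.

The sequence branch is a per-residue MLP mapping the pretrained embedding
``P`` (L x F) to a learned representation ``X`` (L x D):

    X = sigma(... sigma(P W0 + b0) ... W_l + b_l),  sigma = ReLU.

The structure branch is a graph convolutional network over the symmetrically
normalized contact-map adjacency

    A_hat = D^{-1/2} (A + I) D^{-1/2},   D_ii = sum_j (A + I)_ij + c,

with layer rule H' = sigma(A_hat H W) and H0 = X; the output G (L x D) is the
structure representation.  ``c`` is a small positive constant guarding
against empty rows (with the added self-loop, row sums are already >= 1, so
it is a pure safeguard; default 1e-6).

Defaults: MLP depth 2 (F -> D -> D), GCN depth 2 (D -> D each, no bias),
D = 128.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data import ContactMap

__all__ = [
    "MlpParams",
    "GcnParams",
    "NormalizedAdjacency",
    "init_mlp",
    "init_gcn",
    "mlp_forward",
    "normalize_adjacency",
    "gcn_forward",
]


@dataclasses.dataclass
class MlpParams:
    """Weights/biases of the per-residue MLP; dims must chain F -> ... -> D."""

    layers: list  # list of (weight (in, out), bias (out,)) numpy arrays

    def __post_init__(self):
        for k in range(len(self.layers) - 1):
            if self.layers[k][0].shape[1] != self.layers[k + 1][0].shape[0]:
                raise ValueError("MLP layer dimensions do not chain")

    @property
    def in_dim(self) -> int:
        return self.layers[0][0].shape[0]

    @property
    def out_dim(self) -> int:
        return self.layers[-1][0].shape[1]


@dataclasses.dataclass
class GcnParams:
    """Square per-layer weight matrices of the GCN (no bias)."""

    layers: list  # list of (D, D) numpy arrays

    def __post_init__(self):
        for w in self.layers:
            if w.ndim != 2 or w.shape[0] != w.shape[1]:
                raise ValueError("GCN weights must be square (D, D) matrices")


@dataclasses.dataclass
class NormalizedAdjacency:
    """A_hat = D^{-1/2} (A + I) D^{-1/2}; symmetric with nonnegative entries."""

    values: np.ndarray


def _he(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def init_mlp(F: int, D: int, rng: np.random.Generator, depth: int = 2) -> MlpParams:
    """He-initialised MLP F -> D -> ... -> D with ``depth`` layers."""
    dims = [F] + [D] * depth
    layers = [
        (_he(rng, dims[k], (dims[k], dims[k + 1])), np.zeros(dims[k + 1]))
        for k in range(depth)
    ]
    return MlpParams(layers)


def init_gcn(D: int, rng: np.random.Generator, depth: int = 2) -> GcnParams:
    return GcnParams([_he(rng, D, (D, D)) for _ in range(depth)])


def mlp_forward(P, params: MlpParams):
    """Per-residue MLP forward pass; row i of the output depends only on row i.

    Accepts a numpy array or autodiff :class:`Tensor` (L, F); returns the same
    kind.  ReLU after every layer, including the last.
    """
    is_tensor = isinstance(P, Tensor)
    h = P if is_tensor else Tensor(np.asarray(P, dtype=np.float64))
    if h.shape[-1] != params.in_dim:
        raise ValueError(
            f"embedding feature dim {h.shape[-1]} != MLP input dim {params.in_dim}"
        )
    for w, b in params.layers:
        w = w if isinstance(w, Tensor) else Tensor(w)
        b = b if isinstance(b, Tensor) else Tensor(b)
        h = ad.relu(h @ w + b)
    return h if is_tensor else h.data


def normalize_adjacency(A, c: float = 1e-6) -> NormalizedAdjacency:
    """Symmetric normalization of a contact-map adjacency.

    A_tilde = A + I; D_ii = sum_j A_tilde_ij + c; A_hat = D^{-1/2} A_tilde
    D^{-1/2}.  ``A`` may be a :class:`~thermograph.data.ContactMap` or a raw
    square array.
    """
    if c <= 0:
        raise ValueError("c must be positive")
    a = A.values if isinstance(A, ContactMap) else np.asarray(A, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    a_tilde = a + np.eye(a.shape[0])
    degree = a_tilde.sum(axis=1) + c
    d_inv_sqrt = 1.0 / np.sqrt(degree)
    # exactly-symmetric scaling: multiply by the outer product in one step
    a_hat = a_tilde * np.outer(d_inv_sqrt, d_inv_sqrt)
    return NormalizedAdjacency(a_hat)


def gcn_forward(X, A_hat: NormalizedAdjacency, params: GcnParams):
    """GCN forward pass: H^{l+1} = ReLU(A_hat H^l W^l), H^0 = X.

    Accepts numpy arrays or autodiff Tensors for X; A_hat is constant.
    """
    is_tensor = isinstance(X, Tensor)
    h = X if is_tensor else Tensor(np.asarray(X, dtype=np.float64))
    a = Tensor(A_hat.values)
    if a.shape[0] != h.shape[0]:
        raise ValueError(
            f"adjacency size {a.shape[0]} != node count {h.shape[0]}"
        )
    for w in params.layers:
        w = w if isinstance(w, Tensor) else Tensor(w)
        if w.shape[0] != h.shape[-1]:
            raise ValueError("GCN weight dim does not match representation dim")
        h = ad.relu(a @ h @ w)
    return h if is_tensor else h.data
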