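"""Graph-convolutional smoothing of gene features over the interaction network.

The weighted, undirected gene network with adjacency A is turned into the
self-looped, symmetrically normalized propagation operator

    L = D^{-1/2} (A + I) D^{-1/2},   D = diag(rowsum(A + I)),

whose spectrum lies in [-1, 1]. One graph-convolution layer computes
H' = sigma(L H W): each gene's feature becomes a degree-normalized average of
itself and its neighbors, linearly mixed by W. Genes absent from the edge
list are isolated nodes whose self-loop makes their row of L a standard basis
vector, so their features pass through unsmoothed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

RELU = "relu"
IDENTITY = "identity"
ACTIVATIONS = (RELU, IDENTITY)


@dataclasses.dataclass
class GeneNetwork:
    """Weighted undirected gene graph over an ordered gene list."""

    gene_ids: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.gene_ids)
        if self.A.shape != (n, n):
            raise ValidationError(
                f"adjacency shape {self.A.shape} does not match {n} genes"
            )
        if not np.allclose(self.A, self.A.T):
            raise ValidationError("adjacency matrix must be symmetric")
        if np.any(np.diag(self.A) != 0):
            raise ValidationError("adjacency diagonal must be zero (no self-edges)")
        if self.A.min() < 0:
            raise ValidationError("edge weights must be non-negative")

    @classmethod
    def from_edges(cls, gene_ids: Sequence[str], edges: pd.DataFrame) -> "GeneNetwork":
        """Build the dense adjacency over ``gene_ids`` from an edge list.

        Edges touching genes outside ``gene_ids`` are dropped (those genes are
        not part of the feature universe); duplicated (a, b) pairs keep the
        maximum weight. Genes with no surviving edge stay isolated.
        """
        gene_ids = list(gene_ids)
        index = {g: i for i, g in enumerate(gene_ids)}
        A = np.zeros((len(gene_ids), len(gene_ids)))
        for a, b, w in zip(edges["gene_a"], edges["gene_b"], edges["weight"]):
            ia, ib = index.get(a), index.get(b)
            if ia is None or ib is None or ia == ib:
                continue
            w = float(w)
            if w > A[ia, ib]:
                A[ia, ib] = A[ib, ia] = w
        return cls(gene_ids=gene_ids, A=A)


def build_propagation_matrix(network: GeneNetwork) -> np.ndarray:
    """Return L = D^{-1/2} (A + I) D^{-1/2}.

    The self-loop guarantees every degree is >= 1, so the normalization is
    always defined and an isolated node's row equals its basis vector.
    """
    A_tilde = network.A + np.eye(len(network.gene_ids))
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


@dataclasses.dataclass
class GcnLayer:
    """One graph-convolution layer: H -> activation(L H W)."""

    W: np.ndarray
    activation: str = RELU

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if not np.isfinite(self.W).all():
            raise ValidationError("GCN weights must be finite")
        if self.activation not in ACTIVATIONS:
            raise ValidationError(
                f"activation must be one of {ACTIVATIONS}, got {self.activation!r}"
            )

    @classmethod
    def identity(cls, n_features: int) -> "GcnLayer":
        """Pure network smoothing: W = I, no nonlinearity."""
        return cls(W=np.eye(n_features), activation=IDENTITY)


def gcn_propagate(L: np.ndarray, H: np.ndarray, layer: GcnLayer) -> np.ndarray:
    """Apply one layer: activation(L @ H @ W)."""
    L = np.asarray(L, dtype=float)
    H = np.asarray(H, dtype=float)
    if L.shape[1] != H.shape[0]:
        raise ValidationError(
            f"propagation matrix {L.shape} does not conform with features {H.shape}"
        )
    if H.shape[1] != layer.W.shape[0]:
        raise ValidationError(
            f"features {H.shape} do not conform with layer weights {layer.W.shape}"
        )
    Z = L @ H @ layer.W
    if layer.activation == RELU:
        return np.maximum(Z, 0.0)
    return Z


def embed_genes(
    network: GeneNetwork,
    X: np.ndarray,
    layers: Sequence[GcnLayer],
    gene_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Sequentially propagate X through ``layers`` over the network.

    With zero layers the features are returned unchanged. When ``gene_ids``
    is given it must match the network's gene order exactly.
    """
    if gene_ids is not None and list(gene_ids) != list(network.gene_ids):
        raise ValidationError("gene order of features and network differ")
    X = np.asarray(X, dtype=float)
    if X.shape[0] != len(network.gene_ids):
        raise ValidationError(
            f"feature matrix has {X.shape[0]} rows for {len(network.gene_ids)} genes"
        )
    H = X
    if layers:
        L = build_propagation_matrix(network)
        for layer in layers:
            H = gcn_propagate(L, H, layer)
    return H
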