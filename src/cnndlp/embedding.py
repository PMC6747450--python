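"""Pair-embedding matrices for lncRNA-disease node pairs.

For a pair (lncRNA i, disease j) the embedding is a 2 x (Nl + Nd + Nm)
matrix whose columns are blocked [lncRNA | disease | miRNA]:

    row 1: [ L[i, :] | A[i, :] | B[i, :] ]   -- everything about lncRNA i
    row 2: [ A[:, j] | D[j, :] | C[:, j] ]   -- everything about disease j

so each column carries the pair's joint relationship to one third node.
The left embedding X uses the functional/semantic similarities (L, D); the
right embedding Y uses the fused topology similarities (Lc, Dc) in their
place. The adjacent-edge attention reweights X entrywise with a softmax
over each row's columns (see :class:`cnndlp._nn.Attention`).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._nn import softmax

__all__ = [
    "PairEmbedding",
    "AttentionParams",
    "build_left_embedding",
    "build_right_embedding",
    "build_embedding_batch",
    "edge_attention",
    "attention_weights",
]


@dataclasses.dataclass
class AttentionParams:
    """Per-entry attention parameters: scalar -> d_att projection.

    ``W`` and ``b`` project a scalar embedding entry to a d_att vector
    (through tanh); ``u_e`` is the context vector scoring that projection.
    """

    W: np.ndarray
    b: np.ndarray
    u_e: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.atleast_1d(np.asarray(self.W, float))
        self.b = np.atleast_1d(np.asarray(self.b, float))
        self.u_e = np.atleast_1d(np.asarray(self.u_e, float))
        if not (len(self.W) == len(self.b) == len(self.u_e) >= 1):
            raise ValueError("W, b, u_e must share a length d_att >= 1")
        for name, v in (("W", self.W), ("b", self.b), ("u_e", self.u_e)):
            if not np.isfinite(v).all():
                raise ValueError(f"non-finite attention parameter {name}")


@dataclasses.dataclass
class PairEmbedding:
    """Left/right embeddings of one (lncRNA, disease) pair."""

    i: int
    j: int
    X: np.ndarray
    Y: np.ndarray
    X_att: np.ndarray | None = None


def _build(S_l, A, S_d, B, C, i, j) -> np.ndarray:
    nl, nd = A.shape
    nm = B.shape[1]
    if not 0 <= i < nl:
        raise IndexError(f"lncRNA index {i} out of range for Nl={nl}")
    if not 0 <= j < nd:
        raise IndexError(f"disease index {j} out of range for Nd={nd}")
    if S_l.shape != (nl, nl) or S_d.shape != (nd, nd) or C.shape != (nm, nd):
        raise ValueError("matrix shapes inconsistent with A and B")
    x = np.empty((2, nl + nd + nm))
    x[0, :nl] = S_l[i]
    x[0, nl : nl + nd] = A[i]
    x[0, nl + nd :] = B[i]
    x[1, :nl] = A[:, j]
    x[1, nl : nl + nd] = S_d[j]
    x[1, nl + nd :] = C[:, j]
    return x


def build_left_embedding(L, A, D, B, C, i: int, j: int) -> np.ndarray:
    """Left embedding X of pair (i, j) from functional/semantic similarities."""
    return _build(L, A, D, B, C, i, j)


def build_right_embedding(Lc, A, Dc, B, C, i: int, j: int) -> np.ndarray:
    """Right embedding Y of pair (i, j) from fused topology similarities."""
    return _build(Lc, A, Dc, B, C, i, j)


def build_embedding_batch(S_l, A, S_d, B, C, pairs: np.ndarray) -> np.ndarray:
    """Vectorized embedding of many pairs: returns (n_pairs, 2, Nl+Nd+Nm)."""
    pairs = np.asarray(pairs, int)
    ii, jj = pairs[:, 0], pairs[:, 1]
    nl, nd = A.shape
    nm = B.shape[1]
    out = np.empty((len(pairs), 2, nl + nd + nm))
    out[:, 0, :nl] = S_l[ii]
    out[:, 0, nl : nl + nd] = A[ii]
    out[:, 0, nl + nd :] = B[ii]
    out[:, 1, :nl] = A[:, jj].T
    out[:, 1, nl : nl + nd] = S_d[jj]
    out[:, 1, nl + nd :] = C[:, jj].T
    return out


def edge_attention(X: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Apply adjacent-edge attention to an embedding matrix.

    F_ij = tanh(W*X_ij + b); s_ij = F_ij . u_e; alpha = softmax of s over
    the columns of each row; output entry = alpha_ij * X_ij. Rows of alpha
    sum to 1 by construction.
    """
    X = np.asarray(X, float)
    if not np.isfinite(X).all():
        raise ValueError("embedding matrix contains non-finite entries")
    F = np.tanh(X[..., None] * params.W + params.b)
    s = F @ params.u_e
    alpha = softmax(s, axis=-1)
    return alpha * X


def attention_weights(X: np.ndarray, params: AttentionParams) -> np.ndarray:
    """The normalized attention coefficients alpha (same shape as X)."""
    F = np.tanh(np.asarray(X, float)[..., None] * params.W + params.b)
    return softmax(F @ params.u_e, axis=-1)
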