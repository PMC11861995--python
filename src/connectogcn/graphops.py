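"""Graph-convolution kernels: adjacency normalization, the GCN propagation
rule, global pooling, per-layer aggregation summaries, and skip concatenation.

A single GCN layer computes ``H_l = sigma(A* H_{l-1} W + b)`` with ``A*`` the
symmetrically normalized adjacency and ``H_0 = X`` the node feature matrix.
Everything is dense: connectome parcellations are a few hundred regions, so
sparse machinery would add complexity without payoff.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize_adjacency",
    "gcn_layer",
    "global_pool",
    "node_aggregate",
    "concat_skip",
]

ACTIVATIONS = {
    "relu": lambda z: np.maximum(z, 0.0),
    "tanh": np.tanh,
    "identity": lambda z: z,
}


def normalize_adjacency(adjacency: np.ndarray, add_self_loops: bool = True) -> np.ndarray:
    """Symmetric degree normalization ``D̃^(-1/2) (A + I) D̃^(-1/2)``.

    With ``add_self_loops=False`` the identity is omitted and plain
    ``D^(-1/2) A D^(-1/2)`` is returned.  The result has spectral radius at
    most 1.  Isolated nodes (zero degree without a self-loop) map to zero rows
    rather than dividing by zero.

    Raises ``ValueError`` on asymmetric, negative, non-finite or non-square
    input, naming the offending entry.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.isfinite(A).all():
        i, j = np.unravel_index(int(np.flatnonzero(~np.isfinite(A))[0]), A.shape)
        raise ValueError(f"non-finite adjacency entry at ({i},{j})")
    asym = np.abs(A - A.T)
    if asym.max(initial=0.0) > 1e-8 * max(1.0, np.abs(A).max()):
        i, j = np.unravel_index(int(np.argmax(asym)), A.shape)
        raise ValueError(f"adjacency not symmetric at ({i},{j}): {A[i, j]!r} vs {A[j, i]!r}")
    if (A < 0).any():
        i, j = np.unravel_index(int(np.argmin(A)), A.shape)
        raise ValueError(f"negative adjacency entry {A[i, j]!r} at ({i},{j})")

    A = (A + A.T) / 2.0
    if add_self_loops:
        A = A + np.eye(A.shape[0])
    deg = A.sum(axis=1)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
    return dinv[:, None] * A * dinv[None, :]


def gcn_layer(
    H_prev: np.ndarray,
    A_star: np.ndarray,
    W: np.ndarray,
    b: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """One graph-convolution step ``sigma(A* H W + b)``.

    ``H_prev W`` forms each node's outgoing message; left-multiplying by the
    normalized adjacency aggregates messages over weighted neighborhoods; the
    bias is broadcast across nodes.
    """
    H_prev = np.asarray(H_prev, dtype=float)
    A_star = np.asarray(A_star, dtype=float)
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if activation not in ACTIVATIONS:
        raise ValueError(f"unknown activation {activation!r}")
    if not (np.isfinite(W).all() and np.isfinite(b).all()):
        raise ValueError("non-finite weights")
    n = A_star.shape[0]
    if A_star.shape != (n, n):
        raise ValueError(f"A_star must be square, got {A_star.shape}")
    if H_prev.shape[0] != n:
        raise ValueError(f"H has {H_prev.shape[0]} rows but graph has {n} nodes")
    if W.shape[0] != H_prev.shape[1]:
        raise ValueError(f"W input dim {W.shape[0]} != embedding width {H_prev.shape[1]}")
    if b.shape != (W.shape[1],):
        raise ValueError(f"bias shape {b.shape} != ({W.shape[1]},)")
    return ACTIVATIONS[activation](A_star @ H_prev @ W + b)


def global_pool(H: np.ndarray, kind: str = "mean") -> np.ndarray:
    """Column-wise mean or max over nodes: a permutation-invariant graph
    embedding vector of length equal to the embedding width."""
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] == 0:
        raise ValueError("empty node embedding")
    if kind == "mean":
        return H.mean(axis=0)
    if kind == "max":
        return H.max(axis=0)
    raise ValueError(f"unknown pooling kind {kind!r}")


def node_aggregate(H: np.ndarray, kind: str = "mean") -> np.ndarray:
    """Per-layer aggregation summary used between residual blocks.

    Emits one graph-summary vector per layer (the column-wise mean or max of
    the node embeddings) while the node-level stream continues unchanged; the
    readout concatenates these per-layer summaries via :func:`concat_skip`.
    """
    return global_pool(H, kind)


def concat_skip(parts: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-layer summary vectors in layer order.

    With skip connections disabled the caller passes only the final layer's
    summary, so a single part is returned unchanged.
    """
    if len(parts) == 0:
        raise ValueError("concat_skip requires at least one part")
    parts = [np.asarray(p, dtype=float).ravel() for p in parts]
    for k, p in enumerate(parts):
        if not np.isfinite(p).all():
            raise ValueError(f"non-finite entries in part {k}")
    return np.concatenate(parts)
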