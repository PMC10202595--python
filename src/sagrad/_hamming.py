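"""Vectorised Hamming-distance kernels and threshold clustering.

Sequences are equal-length upper-case DNA strings; they are encoded once as
uint8 arrays and compared blockwise so that all-pairs distance computations
on a few thousand unique sequences stay in the tens-of-milliseconds range.
Connected components under a distance threshold are delegated to
scipy.sparse.csgraph.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

_BLOCK = 256  # rows per block in pairwise comparisons; bounds peak memory


def encode(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(seqs[0])
    for s in seqs:
        if len(s) != length:
            raise ValueError(
                f"sequences must have equal length (saw {length} and {len(s)})"
            )
    buf = "".join(seqs).encode("ascii")
    return np.frombuffer(buf, dtype=np.uint8).reshape(len(seqs), length)


def hamming(a: str, b: str) -> int:
    """Hamming distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def pairwise_distances(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Dense (n, m) Hamming distance matrix between encoded sequence sets."""
    n, m = A.shape[0], B.shape[0]
    out = np.empty((n, m), dtype=np.int32)
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        out[start:stop] = (A[start:stop, None, :] != B[None, :, :]).sum(
            axis=2, dtype=np.int32
        )
    return out


def components_within(seqs: Sequence[str], max_dist: int) -> np.ndarray:
    """Connected-component labels linking sequences at Hamming distance <= max_dist.

    The closure is transitive: A-B and B-C links place A and C in one
    component even if d(A, C) > max_dist.
    """
    n = len(seqs)
    if n == 0:
        return np.empty(0, dtype=np.intp)
    enc = encode(seqs)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    for start in range(0, n, _BLOCK):
        stop = min(start + _BLOCK, n)
        d = (enc[start:stop, None, :] != enc[None, :, :]).sum(axis=2, dtype=np.int32)
        r, c = np.nonzero(d <= max_dist)
        rows.append(r + start)
        cols.append(c)
    row = np.concatenate(rows)
    col = np.concatenate(cols)
    adj = coo_matrix((np.ones(row.size, dtype=np.int8), (row, col)), shape=(n, n))
    _, labels = connected_components(adj, directed=False)
    return labels
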