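"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import networkx as nx
from scipy.stats import binom


def brute_partition(seqs: list[str], max_dist: int) -> set[frozenset]:
    """All-pairs Hamming + connected components via networkx.

    Returns the partition of sequence *indices* as a set of frozensets.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(seqs)))
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            d = sum(a != b for a, b in zip(seqs[i], seqs[j]))
            if d <= max_dist:
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def brute_adapter_hit(
    seq: str, adapter: str, max_mismatch: int, min_overlap: int = 8
) -> bool:
    """Sliding comparison at every offset, prefix-overhang at the 3' end."""
    for offset in range(len(seq)):
        overlap = min(len(adapter), len(seq) - offset)
        if overlap < len(adapter) and overlap < min_overlap:
            continue
        mism = sum(
            seq[offset + i] != adapter[i] for i in range(overlap)
        )
        if mism <= max_mismatch:
            return True
    return False


def binom_count_ci(n: int, p: float, conf: float = 0.99) -> tuple[float, float]:
    """Two-sided binomial confidence bounds on a count at success prob p."""
    lo, hi = binom.interval(conf, n, p)
    return float(lo), float(hi)
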