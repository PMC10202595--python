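"""Nearest-haplotype coancestry matrix and population-structure recovery.

A desk-scale stand-in for chromosome-painting coancestry inference
(RADpainter/fineRADstructure semantics, without the MCMC): over the loci
present in *every* individual, each individual "paints" each locus onto the
other individual(s) carrying the nearest haplotype. Summing these
attributions gives a directional individuals x individuals coancestry
matrix whose block structure, after average-linkage clustering of the
symmetrized matrix, reveals populations.

For individual i at locus l, with d(i, j, l) the minimum Hamming distance
between any allele of i and any allele of j, the nearest-neighbour set
N = argmin_j d receives 1/|N| each at entry (i, j); every (i, locus)
contributes exactly 1, so each row sums to the number of shared loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from ._hamming import encode, pairwise_distances
from .assembly import Catalog, MatchSet
from .errors import ConfigValidationError, SagradError


@dataclass
class HaplotypeMatrix:
    """Individuals x loci grid of allele-sequence tuples (1 or 2 per cell).

    Only catalog loci matched by every individual are included.
    """

    individuals: list[str]
    locus_ids: list[int]
    cells: dict[tuple[str, int], tuple[str, ...]]
    populations: Optional[dict[str, str]] = None

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


def build_haplotype_matrix(
    match_sets: dict[str, MatchSet],
    catalog: Catalog,
    populations: Optional[dict[str, str]] = None,
) -> HaplotypeMatrix:
    """Intersect matched catalog loci across individuals and collect alleles."""
    if not match_sets:
        raise ConfigValidationError("need at least one individual")
    for mset in match_sets.values():
        if mset.catalog_fingerprint != catalog.fingerprint:
            raise ConfigValidationError(
                "match sets were not computed against the given catalog"
            )
    individuals = sorted(match_sets)
    shared: Optional[set[int]] = None
    for ind in individuals:
        ids = match_sets[ind].matched_catalog_ids
        shared = ids if shared is None else (shared & ids)
    if not shared:
        raise SagradError("no catalog locus is present in all individuals")
    locus_ids = sorted(shared)
    cells: dict[tuple[str, int], tuple[str, ...]] = {}
    for ind in individuals:
        by_catalog = {
            rec.catalog_id: rec for rec in match_sets[ind].matches.values()
        }
        for cid in locus_ids:
            alleles = tuple(sorted(set(by_catalog[cid].sample_alleles)))
            cells[(ind, cid)] = alleles
    return HaplotypeMatrix(
        individuals=individuals,
        locus_ids=locus_ids,
        cells=cells,
        populations=populations,
    )


@dataclass
class CoancestryMatrix:
    """Directional coancestry values with zero diagonal.

    Row i sums to the number of shared loci (each locus contributes a total
    attribution of 1 from each individual).
    """

    individuals: list[str]
    values: np.ndarray
    order: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def write_tsv(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            fh.write("individual\t" + "\t".join(self.individuals) + "\n")
            for ind, row in zip(self.individuals, self.values):
                fh.write(ind + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def coancestry(hap: HaplotypeMatrix) -> CoancestryMatrix:
    """Paint each (individual, locus) onto the nearest-haplotype neighbours."""
    inds = hap.individuals
    n = len(inds)
    if n < 2 or hap.n_loci < 1:
        raise ConfigValidationError("coancestry needs >=2 individuals and >=1 locus")
    values = np.zeros((n, n), dtype=float)
    for cid in hap.locus_ids:
        allele_lists = [hap.cells[(ind, cid)] for ind in inds]
        flat = [a for alleles in allele_lists for a in alleles]
        owner = np.repeat(
            np.arange(n), [len(alleles) for alleles in allele_lists]
        )
        dist = pairwise_distances(encode(flat), encode(flat))
        # d[i, j] = min over allele pairs between individuals i and j
        d = np.full((n, n), np.iinfo(np.int32).max, dtype=np.int64)
        np.minimum.at(d, (owner[:, None], owner[None, :]), dist)
        np.fill_diagonal(d, np.iinfo(np.int32).max)
        for i in range(n):
            best = d[i].min()
            nearest = np.nonzero(d[i] == best)[0]
            values[i, nearest] += 1.0 / nearest.size
    return CoancestryMatrix(individuals=list(inds), values=values)


def cluster_coancestry(
    mat: CoancestryMatrix, k: Optional[int] = None
) -> CoancestryMatrix:
    """Average-linkage clustering of the symmetrized coancestry matrix.

    The directional matrix is symmetrized as (C + C^T) / 2 and converted to
    a dissimilarity (max - value, zero diagonal). Sets ``mat.order`` (leaf
    order for heat-map display) and, when k is given, ``mat.labels``.
    """
    n = len(mat.individuals)
    if k is not None and (k < 1 or k > n):
        raise ConfigValidationError(f"k={k} outside [1, {n}]")
    sym = (mat.values + mat.values.T) / 2.0
    dissim = sym.max() - sym
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    Z = linkage(condensed, method="average")
    mat.order = leaves_list(Z)
    if k is not None:
        mat.labels = fcluster(Z, t=k, criterion="maxclust")
    return mat


def score_recovery(labels: Sequence, truth_labels: Sequence) -> float:
    """Adjusted Rand Index between inferred and true population labels."""
    if len(labels) != len(truth_labels):
        raise ConfigValidationError("label vectors differ in length")
    return float(adjusted_rand_score(truth_labels, labels))


def within_between_means(
    mat: CoancestryMatrix, populations: dict[str, str]
) -> tuple[float, float]:
    """Mean coancestry within vs between populations (off-diagonal cells)."""
    n = len(mat.individuals)
    within: list[float] = []
    between: list[float] = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            same = populations[mat.individuals[i]] == populations[mat.individuals[j]]
            (within if same else between).append(mat.values[i, j])
    return float(np.mean(within)), float(np.mean(between))
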