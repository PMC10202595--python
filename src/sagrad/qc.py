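"""Per-sample quality and bias metrics for SAG-RAD vs bulk-RAD evaluation.

Covers the four evaluation axes used to judge whether single-cell MDA
libraries approach bulk libraries: (I) locus recovery and replicate
sharing, (II) coverage uniformity (Lorenz curve / Gini coefficient) and
depth distributions, (III) concordance with a bulk catalog, and (IV)
heterozygosity and the allelic-dropout (ADO) rate. Samples recovering too
few loci are excluded from downstream analysis.

Definitions:

* a locus is *heterozygous* when it has more than one allele;
* the ADO rate is the number of matched loci that are homozygous in the
  sample but diploid (>= 2 alleles) in the bulk catalog, relative to the
  total number of matched loci;
* the Lorenz curve plots the cumulative fraction of total reads against
  the cumulative fraction of loci (depths sorted ascending); the diagonal
  is perfectly uniform coverage and the Gini coefficient summarizes the
  deviation (1 minus twice the area under the curve, trapezoidal —
  exact for the piecewise-linear curve).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .assembly import Catalog, Locus, MatchSet
from .errors import ConfigValidationError, UndefinedMetricError

#: minimum retained-locus count for a sample to stay in downstream analysis
DEFAULT_MIN_LOCI = 10000


def loci_per_sample(loci: Sequence[Locus]) -> int:
    """Number of distinct retained loci in a sample."""
    return sum(1 for locus in loci if locus.retained)


def lorenz(depths: Sequence[float]) -> np.ndarray:
    """Lorenz points: (cumulative locus fraction, cumulative read fraction).

    Depths are sorted ascending; the curve starts at (0, 0), ends at
    (1, 1), and is non-decreasing and convex.
    """
    d = np.sort(np.asarray(depths, dtype=float))
    if d.size == 0 or d.sum() <= 0:
        raise UndefinedMetricError("Lorenz curve undefined for all-zero depths")
    if (d < 0).any():
        raise UndefinedMetricError("depths must be non-negative")
    x = np.arange(0, d.size + 1) / d.size
    y = np.concatenate(([0.0], np.cumsum(d) / d.sum()))
    return np.column_stack([x, y])


def gini(depths: Sequence[float]) -> float:
    """Gini coefficient of the per-locus depth distribution, in [0, 1)."""
    points = lorenz(depths)
    area = float(np.trapezoid(points[:, 1], points[:, 0]))
    return 1.0 - 2.0 * area


def depth_summary(
    depths: Sequence[float],
) -> tuple[float, np.ndarray, np.ndarray]:
    """Median depth plus a histogram on decade-spaced bins (1–1000, 10/decade).

    Depths outside [1, 1000] are clipped into the terminal bins so counts
    are conserved. Returns (median, bin_edges, counts).
    """
    d = np.asarray(depths, dtype=float)
    if d.size == 0 or (d <= 0).any():
        raise UndefinedMetricError("depth summary requires positive depths")
    edges = np.logspace(0, 3, 31)
    counts, _ = np.histogram(np.clip(d, edges[0], edges[-1]), bins=edges)
    return float(np.median(d)), edges, counts


def heterozygosity(loci: Sequence[Locus]) -> float:
    """Fraction of retained loci with more than one allele."""
    retained = [locus for locus in loci if locus.retained]
    if not retained:
        raise UndefinedMetricError("heterozygosity undefined for zero loci")
    return sum(locus.n_alleles >= 2 for locus in retained) / len(retained)


def concordance(match_set: MatchSet) -> int:
    """Number of sample loci with a unique match in the (bulk) catalog."""
    return len(match_set.matches)


def ado_rate(
    match_set: MatchSet,
    bulk_catalog: Catalog,
    diploid_denominator: bool = False,
) -> float:
    """Allelic-dropout rate of a sample against a bulk catalog.

    Numerator: matched loci that are homozygous in the sample while their
    catalog locus carries >= 2 alleles. Denominator: all matched loci, or —
    with ``diploid_denominator`` — only those matching diploid catalog
    loci (an alternative normalization, off by default).
    """
    if match_set.catalog_fingerprint != bulk_catalog.fingerprint:
        raise ConfigValidationError("match set was not computed against this catalog")
    if not match_set.matches:
        raise UndefinedMetricError("ADO rate undefined with zero matched loci")
    by_id = {locus.catalog_id: locus for locus in bulk_catalog.loci}
    n_ado = 0
    n_diploid = 0
    for rec in match_set.matches.values():
        diploid = by_id[rec.catalog_id].diploid
        n_diploid += diploid
        if diploid and rec.homozygous:
            n_ado += 1
    denom = n_diploid if diploid_denominator else len(match_set.matches)
    if denom == 0:
        return 0.0
    return n_ado / denom


@dataclass
class SharingTable:
    """Locus sharing among clonal replicates matched to one common catalog.

    ``k_counts[k]`` is the number of catalog loci found in exactly k of the
    replicates; ``subset_counts`` gives the count per exact replicate
    subset.
    """

    group: tuple[str, ...]
    k_counts: dict[int, int]
    subset_counts: dict[frozenset, int]

    @property
    def n_loci_any(self) -> int:
        return sum(self.k_counts.values())


def sharing_table(match_sets: dict[str, MatchSet]) -> SharingTable:
    """Tabulate how many replicates each catalog locus was recovered in."""
    if not match_sets:
        raise ConfigValidationError("sharing_table needs at least one replicate")
    fingerprints = {m.catalog_fingerprint for m in match_sets.values()}
    if len(fingerprints) != 1:
        raise ConfigValidationError(
            "replicates were matched against different catalogs"
        )
    group = tuple(sorted(match_sets))
    membership: dict[int, set[str]] = {}
    for rep, mset in match_sets.items():
        for cid in mset.matched_catalog_ids:
            membership.setdefault(cid, set()).add(rep)
    k_counts = {k: 0 for k in range(1, len(group) + 1)}
    subset_counts: dict[frozenset, int] = {}
    for members in membership.values():
        k_counts[len(members)] += 1
        key = frozenset(members)
        subset_counts[key] = subset_counts.get(key, 0) + 1
    return SharingTable(group=group, k_counts=k_counts, subset_counts=subset_counts)


@dataclass
class QCReport:
    """One sample's QC row."""

    sample_id: str
    n_loci: int
    gini: Optional[float] = None
    lorenz_points: Optional[np.ndarray] = None
    depth_median: Optional[float] = None
    depth_histogram: Optional[tuple[np.ndarray, np.ndarray]] = None
    n_matched_bulk: Optional[int] = None
    prop_heterozygous: Optional[float] = None
    ado: Optional[float] = None
    retained: bool = True
    min_loci: int = DEFAULT_MIN_LOCI


def qc_report(
    sample_id: str,
    loci: Sequence[Locus],
    bulk_match: Optional[MatchSet] = None,
    bulk_catalog: Optional[Catalog] = None,
    min_loci: int = DEFAULT_MIN_LOCI,
) -> QCReport:
    """Assemble the per-sample QC report from retained loci and bulk matches."""
    retained_loci = [locus for locus in loci if locus.retained]
    n = len(retained_loci)
    report = QCReport(sample_id=sample_id, n_loci=n, min_loci=min_loci)
    report.retained = n >= min_loci
    if n:
        depths = [locus.total_depth for locus in retained_loci]
        report.gini = gini(depths)
        report.lorenz_points = lorenz(depths)
        median, edges, counts = depth_summary(depths)
        report.depth_median = median
        report.depth_histogram = (edges, counts)
        report.prop_heterozygous = heterozygosity(retained_loci)
    if bulk_match is not None and bulk_catalog is not None:
        report.n_matched_bulk = concordance(bulk_match)
        if bulk_match.matches:
            report.ado = ado_rate(bulk_match, bulk_catalog)
    return report


def sample_dropout(
    reports: Sequence[QCReport], min_loci: int = DEFAULT_MIN_LOCI
) -> tuple[list[str], list[str]]:
    """Split samples into (retained, excluded) by the locus-count floor.

    Exclusion is strict: a sample with fewer than ``min_loci`` retained
    loci is dropped; exactly ``min_loci`` is kept.
    """
    retained: list[str] = []
    excluded: list[str] = []
    for report in reports:
        report.retained = report.n_loci >= min_loci
        (retained if report.retained else excluded).append(report.sample_id)
    return retained, excluded


def write_qc_table(reports: Sequence[QCReport], path: Path | str) -> None:
    def fmt(value, digits=6):
        return "." if value is None else f"{value:.{digits}g}"

    with open(path, "w") as fh:
        fh.write(
            "sample_id\tn_loci\tgini\tdepth_median\tn_matched_bulk\t"
            "prop_heterozygous\tado_rate\tretained\n"
        )
        for r in reports:
            fh.write(
                f"{r.sample_id}\t{r.n_loci}\t{fmt(r.gini)}\t{fmt(r.depth_median)}\t"
                f"{'.' if r.n_matched_bulk is None else r.n_matched_bulk}\t"
                f"{fmt(r.prop_heterozygous)}\t{fmt(r.ado)}\t"
                f"{int(r.retained)}\n"
            )


def write_lorenz_points(reports: Sequence[QCReport], path: Path | str) -> None:
    """Long-format Lorenz points per sample, ready for plotting."""
    with open(path, "w") as fh:
        fh.write("sample_id\tfrac_loci\tfrac_reads\n")
        for r in reports:
            if r.lorenz_points is None:
                continue
            for x, y in r.lorenz_points:
                fh.write(f"{r.sample_id}\t{x:.6f}\t{y:.6f}\n")


def write_sharing_table(table: SharingTable, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#group={','.join(table.group)}\n")
        fh.write("k\tn_loci\n")
        for k in sorted(table.k_counts):
            fh.write(f"{k}\t{table.k_counts[k]}\n")
        fh.write("#subset_counts\n")
        for subset, count in sorted(
            table.subset_counts.items(), key=lambda kv: sorted(kv[0])
        ):
            fh.write(f"{'+'.join(sorted(subset))}\t{count}\n")
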