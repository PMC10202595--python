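"""De-novo RAD locus assembly: stacks, loci, cross-sample catalog, matching.

A deliberately transparent reimplementation of the classic de-novo RADseq
path (ustacks / cstacks / sstacks semantics) for substitution-only data:

* PCR duplicates are removed by (read-1 sequence, insert length) identity;
* identical reads are grouped into *stacks*; stacks of depth >= m are
  primary, the rest are secondary reads;
* primary stacks within Hamming distance M of each other (transitively
  closed) merge into a *locus* whose alleles are the member stacks;
* secondary reads are absorbed into their unique nearest allele within a
  distance cap, updating depths;
* loci with more than three allele-forming stacks (*confounded*, typically
  repeats or amplification artifacts) and loci with extreme coverage
  (total depth > mean + 3 SD over the sample's loci, computed before any
  removal) are filtered out;
* per-sample loci merge across samples into a *catalog* at consensus
  distance <= n, and sample loci are matched back against the catalog,
  requiring a unique minimum-distance hit within n.

Defaults m=3, M=2, n=2 are the standard configuration for this kind of
single-digest RAD data. All merging uses transitive closure, which is
deterministic and order-independent.
"""

from __future__ import annotations

import hashlib
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from ._hamming import components_within, encode, pairwise_distances
from .errors import ConfigValidationError
from .io import ReadRecord


@dataclass
class Stack:
    """A group of identical reads: one putative allele observation."""

    consensus: str
    depth: int
    members: list[str] = field(default_factory=list)


@dataclass
class Allele:
    seq: str
    depth: int


@dataclass
class Locus:
    """A putative RAD locus: one or more alleles merged from nearby stacks."""

    locus_id: int
    consensus: str
    alleles: list[Allele]
    n_stacks: int
    confounded: bool = False
    extreme_coverage: bool = False

    @property
    def total_depth(self) -> int:
        return sum(a.depth for a in self.alleles)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def retained(self) -> bool:
        return not (self.confounded or self.extreme_coverage)

    @property
    def snp_positions(self) -> list[int]:
        if len(self.alleles) < 2:
            return []
        enc = encode([a.seq for a in self.alleles])
        return np.nonzero((enc != enc[0]).any(axis=0))[0].tolist()


@dataclass
class CatalogLocus:
    catalog_id: int
    consensus: str
    alleles: frozenset[str]
    contributors: list[tuple[str, int]]  # (sample_id, sample locus_id)

    @property
    def diploid(self) -> bool:
        return len(self.alleles) >= 2


@dataclass
class Catalog:
    """Cross-sample merged locus set; ``n`` is the merge distance used."""

    loci: list[CatalogLocus]
    n: int

    def __post_init__(self) -> None:
        digest = hashlib.sha1()
        for locus in self.loci:
            digest.update(locus.consensus.encode())
            for allele in sorted(locus.alleles):
                digest.update(allele.encode())
        self.fingerprint = digest.hexdigest()

    def __len__(self) -> int:
        return len(self.loci)


@dataclass
class MatchRecord:
    sample_locus_id: int
    catalog_id: int
    distance: int
    sample_alleles: tuple[str, ...]
    catalog_alleles_present: tuple[str, ...]

    @property
    def homozygous(self) -> bool:
        return len(self.sample_alleles) == 1


@dataclass
class MatchSet:
    """One sample's assignment of loci to catalog loci."""

    sample_id: str
    catalog_fingerprint: str
    matches: dict[int, MatchRecord]
    ambiguous: list[int]
    unmatched: list[int]

    @property
    def matched_catalog_ids(self) -> set[int]:
        return {m.catalog_id for m in self.matches.values()}


def dedup_pcr(reads: Iterable[ReadRecord]) -> tuple[list[ReadRecord], int]:
    """Remove PCR duplicates: keep the first pair per (read-1 sequence, insert).

    Pairs sharing both read-1 sequence and insert length cannot be told
    apart from library-amplification copies; distinct inserts are
    independent molecules and are kept.
    """
    seen: set[tuple[str, int]] = set()
    kept: list[ReadRecord] = []
    removed = 0
    for read in reads:
        if read.insert is None:
            raise ConfigValidationError(
                f"read {read.read_id!r} has no insert length; cannot deduplicate"
            )
        key = (read.seq1, read.insert)
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(read)
    return kept, removed


def build_stacks(
    reads: Iterable[ReadRecord], m: int = 3
) -> tuple[list[Stack], list[ReadRecord]]:
    """Group identical read-1 sequences; depth >= m forms a primary stack."""
    reads = list(reads)
    if reads:
        length = len(reads[0].seq1)
        if any(len(r.seq1) != length for r in reads):
            raise ConfigValidationError("reads must have equal length to stack")
    groups: dict[str, list[ReadRecord]] = {}
    for read in reads:
        groups.setdefault(read.seq1, []).append(read)
    stacks: list[Stack] = []
    secondary: list[ReadRecord] = []
    for seq in sorted(groups):
        members = groups[seq]
        if len(members) >= m:
            stacks.append(Stack(seq, len(members), [r.read_id for r in members]))
        else:
            secondary.extend(members)
    return stacks, secondary


def _order_alleles(alleles: list[Allele]) -> list[Allele]:
    return sorted(alleles, key=lambda a: (-a.depth, a.seq))


def merge_stacks(stacks: list[Stack], M: int = 2) -> list[Locus]:
    """Merge stacks within Hamming distance M (transitive closure) into loci.

    Alleles are the member stacks with their depths; the consensus is the
    deepest allele (ties broken lexicographically).
    """
    if not stacks:
        return []
    stacks = sorted(stacks, key=lambda s: s.consensus)
    labels = components_within([s.consensus for s in stacks], M)
    grouped: dict[int, list[Stack]] = {}
    for stack, label in zip(stacks, labels):
        grouped.setdefault(int(label), []).append(stack)
    loci: list[Locus] = []
    components = sorted(grouped.values(), key=lambda g: g[0].consensus)
    for locus_id, members in enumerate(components):
        alleles = _order_alleles([Allele(s.consensus, s.depth) for s in members])
        loci.append(
            Locus(
                locus_id=locus_id,
                consensus=alleles[0].seq,
                alleles=alleles,
                n_stacks=len(members),
            )
        )
    return loci


def absorb_secondary(
    loci: list[Locus], secondary: list[ReadRecord], max_dist: int = 4
) -> tuple[int, int]:
    """Assign each secondary read to its unique nearest allele within max_dist.

    Reads tied between alleles, or farther than ``max_dist`` from every
    allele, are dropped. Returns (absorbed, dropped) counts; allele depths
    are updated in place.
    """
    if not secondary:
        return 0, 0
    if not loci:
        return 0, len(secondary)
    allele_refs = [
        (locus, allele) for locus in loci for allele in locus.alleles
    ]
    allele_enc = encode([a.seq for _, a in allele_refs])
    counts = Counter(r.seq1 for r in secondary)
    uniq = sorted(counts)
    dist = pairwise_distances(encode(uniq), allele_enc)
    absorbed = dropped = 0
    for row, seq in enumerate(uniq):
        d = dist[row]
        best = int(d.min())
        if best > max_dist or int((d == best).sum()) != 1:
            dropped += counts[seq]
            continue
        _, allele = allele_refs[int(d.argmin())]
        allele.depth += counts[seq]
        absorbed += counts[seq]
    return absorbed, dropped


@dataclass
class LocusFilterResult:
    retained: list[Locus]
    n_confounded: int
    n_extreme: int
    n_input: int
    depth_threshold: Optional[float]

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def filter_loci(loci: list[Locus]) -> LocusFilterResult:
    """Apply the confounded and extreme-coverage locus filters.

    Confounded: more than three allele-forming stacks. Extreme coverage:
    total depth above mean + 3 x SD of the sample's per-locus depths,
    with the statistics computed over all loci before any removal. Both
    usually indicate repetitive regions or biased amplification.
    """
    threshold: Optional[float] = None
    if len(loci) >= 2:
        depths = np.array([locus.total_depth for locus in loci], dtype=float)
        threshold = float(depths.mean() + 3.0 * depths.std())
    elif loci:
        warnings.warn(
            "fewer than 2 loci: depth SD undefined, skipping extreme-coverage filter",
            stacklevel=2,
        )
    n_confounded = n_extreme = 0
    retained: list[Locus] = []
    for locus in loci:
        locus.confounded = locus.n_stacks > 3
        locus.extreme_coverage = (
            threshold is not None and locus.total_depth > threshold
        )
        n_confounded += locus.confounded
        n_extreme += locus.extreme_coverage
        if locus.retained:
            retained.append(locus)
    return LocusFilterResult(
        retained=retained,
        n_confounded=n_confounded,
        n_extreme=n_extreme,
        n_input=len(loci),
        depth_threshold=threshold,
    )


def build_catalog(sample_loci: dict[str, list[Locus]], n: int = 2) -> Catalog:
    """Merge loci across samples into a catalog at consensus distance <= n.

    A catalog locus's allele set is the union of its members' alleles; its
    consensus is the member consensus with the highest summed depth (ties
    broken lexicographically).
    """
    if not sample_loci:
        raise ConfigValidationError("build_catalog needs at least one sample")
    entries: list[tuple[str, Locus]] = [
        (sample, locus)
        for sample in sorted(sample_loci)
        for locus in sample_loci[sample]
    ]
    if not entries:
        return Catalog(loci=[], n=n)
    lengths = {len(locus.consensus) for _, locus in entries}
    if len(lengths) != 1:
        raise ConfigValidationError("inconsistent locus lengths across samples")

    uniq = sorted({locus.consensus for _, locus in entries})
    labels = components_within(uniq, n)
    label_of = {seq: int(lab) for seq, lab in zip(uniq, labels)}
    grouped: dict[int, list[tuple[str, Locus]]] = {}
    for sample, locus in entries:
        grouped.setdefault(label_of[locus.consensus], []).append((sample, locus))

    components = sorted(
        grouped.values(), key=lambda g: min(loc.consensus for _, loc in g)
    )
    catalog_loci: list[CatalogLocus] = []
    for catalog_id, members in enumerate(components):
        depth_by_consensus: dict[str, int] = {}
        alleles: set[str] = set()
        contributors: list[tuple[str, int]] = []
        for sample, locus in members:
            depth_by_consensus[locus.consensus] = (
                depth_by_consensus.get(locus.consensus, 0) + locus.total_depth
            )
            alleles.update(a.seq for a in locus.alleles)
            contributors.append((sample, locus.locus_id))
        consensus = min(
            depth_by_consensus, key=lambda s: (-depth_by_consensus[s], s)
        )
        catalog_loci.append(
            CatalogLocus(catalog_id, consensus, frozenset(alleles), contributors)
        )
    return Catalog(loci=catalog_loci, n=n)


def match_to_catalog(
    loci: list[Locus], catalog: Catalog, sample_id: str = "", n: Optional[int] = None
) -> MatchSet:
    """Match sample loci against a catalog by minimum consensus distance.

    A locus matches the catalog locus with the minimum Hamming distance,
    provided that minimum is <= n and unique; ties are recorded as
    ambiguous and excluded from matched counts.
    """
    max_dist = catalog.n if n is None else n
    matches: dict[int, MatchRecord] = {}
    ambiguous: list[int] = []
    unmatched: list[int] = []
    if not loci or not catalog.loci:
        return MatchSet(sample_id, catalog.fingerprint, matches, ambiguous,
                        [locus.locus_id for locus in loci])
    cat_enc = encode([c.consensus for c in catalog.loci])
    dist = pairwise_distances(encode([locus.consensus for locus in loci]), cat_enc)
    for row, locus in enumerate(loci):
        d = dist[row]
        best = int(d.min())
        if best > max_dist:
            unmatched.append(locus.locus_id)
            continue
        if int((d == best).sum()) != 1:
            ambiguous.append(locus.locus_id)
            continue
        cat = catalog.loci[int(d.argmin())]
        sample_alleles = tuple(a.seq for a in locus.alleles)
        present = tuple(sorted(set(sample_alleles) & cat.alleles))
        matches[locus.locus_id] = MatchRecord(
            sample_locus_id=locus.locus_id,
            catalog_id=cat.catalog_id,
            distance=best,
            sample_alleles=sample_alleles,
            catalog_alleles_present=present,
        )
    return MatchSet(sample_id, catalog.fingerprint, matches, ambiguous, unmatched)


@dataclass
class SampleAssembly:
    """Full assembly record for one sample, with read-conservation accounting."""

    sample_id: str
    loci: list[Locus]
    filter_result: LocusFilterResult
    n_reads_in: int
    n_duplicates_removed: int
    n_in_stacks: int
    n_secondary_absorbed: int
    n_secondary_dropped: int

    @property
    def retained_loci(self) -> list[Locus]:
        return self.filter_result.retained


def assemble_sample(
    reads: Iterable[ReadRecord],
    sample_id: str = "",
    m: int = 3,
    M: int = 2,
    absorb_max_dist: int = 4,
    dedup: bool = True,
) -> SampleAssembly:
    """Run the per-sample assembly chain: dedup -> stacks -> loci -> filters."""
    reads = list(reads)
    n_in = len(reads)
    removed = 0
    if dedup:
        reads, removed = dedup_pcr(reads)
    stacks, secondary = build_stacks(reads, m=m)
    loci = merge_stacks(stacks, M=M)
    absorbed, dropped = absorb_secondary(loci, secondary, max_dist=absorb_max_dist)
    result = filter_loci(loci)
    return SampleAssembly(
        sample_id=sample_id,
        loci=loci,
        filter_result=result,
        n_reads_in=n_in,
        n_duplicates_removed=removed,
        n_in_stacks=sum(s.depth for s in stacks),
        n_secondary_absorbed=absorbed,
        n_secondary_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# plain-text interchange (locus tables, catalog, match tables)

def write_locus_table(loci: list[Locus], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "locus_id\tconsensus\tn_alleles\tallele_seqs\tallele_depths\t"
            "total_depth\tn_stacks\tstatus\n"
        )
        for locus in loci:
            status = (
                "retained" if locus.retained
                else ("confounded" if locus.confounded else "extreme_coverage")
            )
            fh.write(
                f"{locus.locus_id}\t{locus.consensus}\t{locus.n_alleles}\t"
                f"{','.join(a.seq for a in locus.alleles)}\t"
                f"{','.join(str(a.depth) for a in locus.alleles)}\t"
                f"{locus.total_depth}\t{locus.n_stacks}\t{status}\n"
            )


def read_locus_table(path: Path | str) -> list[Locus]:
    loci: list[Locus] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("locus_id\t"):
            raise ConfigValidationError(f"{path}: not a locus table")
        for line in fh:
            (lid, consensus, _n, seqs, depths, _total, n_stacks, status) = (
                line.rstrip("\n").split("\t")
            )
            alleles = [
                Allele(s, int(d))
                for s, d in zip(seqs.split(","), depths.split(","))
            ]
            loci.append(
                Locus(
                    locus_id=int(lid),
                    consensus=consensus,
                    alleles=alleles,
                    n_stacks=int(n_stacks),
                    confounded=status == "confounded",
                    extreme_coverage=status == "extreme_coverage",
                )
            )
    return loci


def write_catalog(catalog: Catalog, fasta_path: Path | str, tsv_path: Path | str) -> None:
    """Catalog consensus FASTA (headers carry allele counts) + full TSV."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(locus.consensus),
            id=f"CL{locus.catalog_id:06d}",
            description=f"n_alleles={len(locus.alleles)}",
        )
        for locus in catalog.loci
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(tsv_path, "w") as fh:
        fh.write(f"#n={catalog.n}\tfingerprint={catalog.fingerprint}\n")
        fh.write("catalog_id\tconsensus\talleles\tcontributors\n")
        for locus in catalog.loci:
            contribs = ",".join(f"{s}:{lid}" for s, lid in locus.contributors)
            fh.write(
                f"{locus.catalog_id}\t{locus.consensus}\t"
                f"{','.join(sorted(locus.alleles))}\t{contribs}\n"
            )


def read_catalog(tsv_path: Path | str) -> Catalog:
    loci: list[CatalogLocus] = []
    with open(tsv_path) as fh:
        meta = fh.readline().lstrip("#").rstrip("\n").split("\t")
        n = int(meta[0].partition("=")[2])
        fh.readline()  # column header
        for line in fh:
            cid, consensus, alleles, contribs = line.rstrip("\n").split("\t")
            contributors = []
            if contribs:
                for item in contribs.split(","):
                    sample, _, lid = item.rpartition(":")
                    contributors.append((sample, int(lid)))
            loci.append(
                CatalogLocus(
                    int(cid), consensus, frozenset(alleles.split(",")), contributors
                )
            )
    return Catalog(loci=loci, n=n)


def write_match_table(match_set: MatchSet, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"#sample={match_set.sample_id}\t"
            f"fingerprint={match_set.catalog_fingerprint}\n"
        )
        fh.write(
            "sample_locus\tcatalog_locus\tdistance\tsample_alleles\t"
            "catalog_alleles_present\n"
        )
        for rec in match_set.matches.values():
            fh.write(
                f"{rec.sample_locus_id}\t{rec.catalog_id}\t{rec.distance}\t"
                f"{','.join(rec.sample_alleles)}\t"
                f"{','.join(rec.catalog_alleles_present)}\n"
            )
        for lid in match_set.ambiguous:
            fh.write(f"{lid}\tambiguous\t.\t.\t.\n")
        for lid in match_set.unmatched:
            fh.write(f"{lid}\tunmatched\t.\t.\t.\n")


def read_match_table(path: Path | str) -> MatchSet:
    with open(path) as fh:
        meta = fh.readline().lstrip("#").rstrip("\n").split("\t")
        sample = meta[0].partition("=")[2]
        fingerprint = meta[1].partition("=")[2]
        fh.readline()
        matches: dict[int, MatchRecord] = {}
        ambiguous: list[int] = []
        unmatched: list[int] = []
        for line in fh:
            lid, cat, dist, alleles, present = line.rstrip("\n").split("\t")
            if cat == "ambiguous":
                ambiguous.append(int(lid))
            elif cat == "unmatched":
                unmatched.append(int(lid))
            else:
                matches[int(lid)] = MatchRecord(
                    int(lid),
                    int(cat),
                    int(dist),
                    tuple(alleles.split(",")),
                    tuple(present.split(",")) if present else (),
                )
    return MatchSet(sample, fingerprint, matches, ambiguous, unmatched)
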