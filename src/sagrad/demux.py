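"""Inline-barcode demultiplexing and read filtering.

Mirrors the standard RADseq intake path: reads are binned by their 7-bp
inline barcode (one mismatch rescued when unambiguous), then pass an ordered
battery of whole-read filters — intact SbfI cut-site remnant, no uncalled
bases, sliding-window quality, adapter contamination — followed by a
k-mer presence screen against a contaminant reference that stands in for a
taxonomic classifier. A read pair lands in exactly one bin: a sample, or
the discard category of the *first* failing filter. Filters are applied to
both mates (a documented assumption; only read-1 carries barcode and
cut-site).

No quality trimming is performed: reads are kept or discarded whole.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np

from ._hamming import hamming
from .errors import ConfigValidationError, FastqFormatError
from .io import DISCARD_REASONS, ReadRecord, read_fastq_pairs, revcomp
from .simulate import CUTSITE_REMNANT


@dataclass
class SampleSheet:
    """Mapping sample id -> inline barcode.

    Barcodes must be unique and equal-length; pairwise Hamming distance < 3
    makes 1-mismatch rescue ambiguous and is reported as a warning rather
    than an error so that real, imperfect designs can still be processed.
    """

    barcodes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.barcodes:
            raise ConfigValidationError("sample sheet is empty")
        lengths = {len(b) for b in self.barcodes.values()}
        if len(lengths) != 1:
            raise ConfigValidationError("barcodes must all have the same length")
        values = list(self.barcodes.values())
        if len(set(values)) != len(values):
            raise ConfigValidationError("barcodes must be unique")
        for i, a in enumerate(values):
            for b in values[i + 1 :]:
                if hamming(a, b) < 3:
                    warnings.warn(
                        f"barcodes {a} and {b} are within Hamming distance 2; "
                        "1-mismatch rescue may be ambiguous",
                        stacklevel=2,
                    )
        self._by_barcode = {b: s for s, b in self.barcodes.items()}

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes.values())))

    @classmethod
    def from_tsv(cls, path: Path | str) -> "SampleSheet":
        barcodes: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("sample_id\t"):
                    continue
                sample, barcode = line.split("\t")[:2]
                barcodes[sample] = barcode
        return cls(barcodes)

    def to_tsv(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tbarcode\n")
            for sample, barcode in self.barcodes.items():
                fh.write(f"{sample}\t{barcode}\n")


def assign_barcode(
    read: ReadRecord, sheet: SampleSheet, max_mismatch: int = 1
) -> Optional[str]:
    """Assign a read pair to a sample by its read-1 prefix barcode.

    An exact match wins; otherwise the unique barcode within
    ``max_mismatch`` wins (barcode rescue). Ties are discarded as
    ``ambiguous_barcode``, no match as ``no_barcode``. On assignment the
    barcode is trimmed from seq1/qual1 and nothing else is altered.
    """
    bl = sheet.barcode_length
    if len(read.seq1) < bl:
        read.discard_reason = "no_barcode"
        return None
    prefix = read.seq1[:bl]
    sample = sheet._by_barcode.get(prefix)
    if sample is None and max_mismatch > 0:
        hits = [
            s
            for b, s in sheet._by_barcode.items()
            if hamming(prefix, b) <= max_mismatch
        ]
        if len(hits) == 1:
            sample = hits[0]
        elif len(hits) > 1:
            read.discard_reason = "ambiguous_barcode"
            return None
    if sample is None:
        read.discard_reason = "no_barcode"
        return None
    read.assigned_sample = sample
    read.seq1 = read.seq1[bl:]
    read.qual1 = read.qual1[bl:]
    return sample


def check_cutsite(read: ReadRecord, remnant: str = CUTSITE_REMNANT) -> bool:
    """Pass iff the barcode-trimmed read-1 begins with the exact remnant."""
    if read.seq1.startswith(remnant):
        return True
    read.discard_reason = "no_cutsite"
    return False


def filter_uncalled(read: ReadRecord) -> bool:
    """Pass iff neither mate contains an uncalled base (N)."""
    if "N" in read.seq1 or "N" in read.seq2:
        read.discard_reason = "uncalled_base"
        return False
    return True


def _phred(qual: str) -> np.ndarray:
    scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(int) - 33
    if scores.size and (scores.min() < 0 or scores.max() > 93):
        raise FastqFormatError("quality string is not valid Phred+33")
    return scores


def filter_quality(
    read: ReadRecord, window_frac: float = 0.15, phred_floor: float = 10.0
) -> bool:
    """Sliding-window quality filter on both mates.

    Fails iff any window of length ceil(window_frac x read length) has mean
    Phred score below ``phred_floor``. Reads shorter than the window are
    judged on their whole-read mean.
    """
    for qual in (read.qual1, read.qual2):
        if qual and ord(min(qual)) - 33 >= phred_floor and ord(max(qual)) <= 126:
            continue  # every base already clears the floor
        scores = _phred(qual)
        if scores.size == 0:
            continue
        window = min(max(1, math.ceil(window_frac * scores.size)), scores.size)
        csum = np.concatenate(([0], np.cumsum(scores)))
        means = (csum[window:] - csum[:-window]) / window
        if means.min() < phred_floor:
            read.discard_reason = "low_quality"
            return False
    return True


def _adapter_hit(seq: str, adapter: str, max_mismatch: int, min_overlap: int) -> bool:
    enc_seq = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    enc_ad = np.frombuffer(adapter.encode("ascii"), dtype=np.uint8)
    n, m = enc_seq.size, enc_ad.size
    for offset in range(0, n):
        overlap = min(m, n - offset)
        if overlap < m and overlap < min_overlap:
            break  # overlaps only shrink from here
        mism = int((enc_seq[offset : offset + overlap] != enc_ad[:overlap]).sum())
        if mism <= max_mismatch:
            return True
    return False


def filter_adapter(
    read: ReadRecord,
    adapter: str,
    max_mismatch: int = 2,
    min_overlap: int = 8,
) -> bool:
    """Fail iff the adapter occurs in either mate with <= max_mismatch substitutions.

    A partial adapter hanging off the 3' end counts when the overlap is at
    least ``min_overlap`` bp.
    """
    if len(adapter) > len(read.seq1):
        raise ConfigValidationError("adapter longer than read")
    for seq in (read.seq1, read.seq2):
        if _adapter_hit(seq, adapter, max_mismatch, min_overlap):
            read.discard_reason = "adapter"
            return False
    return True


class KmerIndex:
    """Exact k-mer presence index over a contaminant reference (both strands).

    A reproducible stand-in for taxonomic read classification: a read is
    called contaminant when at least ``min_hit_frac`` of its k-mers occur in
    the index.
    """

    def __init__(self, sequences: Iterable[str], k: int = 31):
        if k < 1:
            raise ConfigValidationError("k must be >= 1")
        self.k = k
        self._kmers: set[str] = set()
        n_seqs = 0
        for seq in sequences:
            n_seqs += 1
            seq = seq.upper()
            for strand in (seq, revcomp(seq)):
                for i in range(len(strand) - k + 1):
                    self._kmers.add(strand[i : i + k])
        if n_seqs == 0 or not self._kmers:
            raise ConfigValidationError("contaminant reference is empty")

    @classmethod
    def from_fasta(cls, path: Path | str, k: int = 31) -> "KmerIndex":
        from Bio import SeqIO

        return cls((str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")), k=k)

    def hit_fraction(self, read: ReadRecord) -> float:
        """Fraction of the pair's k-mers present in the index."""
        hits = 0
        total = 0
        for seq in (read.seq1, read.seq2):
            if len(seq) < self.k:
                raise ConfigValidationError(
                    f"k={self.k} exceeds read length {len(seq)}"
                )
            for i in range(len(seq) - self.k + 1):
                total += 1
                if seq[i : i + self.k] in self._kmers:
                    hits += 1
        return hits / total if total else 0.0

    def is_contaminant(self, read: ReadRecord, min_hit_frac: float = 0.5) -> bool:
        return self.hit_fraction(read) >= min_hit_frac


def screen_contaminants(
    reads: Iterable[ReadRecord],
    index: KmerIndex,
    min_hit_frac: float = 0.5,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Partition reads into (kept, contaminant) by k-mer hit fraction."""
    kept: list[ReadRecord] = []
    flagged: list[ReadRecord] = []
    for read in reads:
        if index.is_contaminant(read, min_hit_frac):
            read.discard_reason = "contaminant"
            flagged.append(read)
        else:
            kept.append(read)
    return kept, flagged


@dataclass
class DemuxConfig:
    """Filter parameters of the demultiplexing stage."""

    max_barcode_mismatch: int = 1
    cutsite: str = CUTSITE_REMNANT
    window_frac: float = 0.15
    phred_floor: float = 10.0
    adapter: Optional[str] = None
    adapter_max_mismatch: int = 2
    screen_k: int = 31
    screen_min_hit_frac: float = 0.5


@dataclass
class DemuxResult:
    """Per-sample read bins plus discard accounting; conserves input count."""

    by_sample: dict[str, list[ReadRecord]]
    discards: dict[str, int]
    n_input: int

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.by_sample.values())

    def accounting(self) -> dict[str, int]:
        table = {"input": self.n_input, "assigned": self.n_assigned}
        table.update(self.discards)
        return table

    def write_accounting(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            for key, value in self.accounting().items():
                fh.write(f"{key}\t{value}\n")


def demultiplex(
    reads: Union[Iterable[ReadRecord], tuple[Path | str, Path | str]],
    sheet: SampleSheet,
    config: DemuxConfig | None = None,
    contaminant_index: Optional[KmerIndex] = None,
) -> DemuxResult:
    """Demultiplex and filter a pooled paired-end read stream.

    ``reads`` is either an iterable of :class:`ReadRecord` or an
    ``(r1_path, r2_path)`` pair of FASTQ files. Filter order is fixed:
    barcode -> cut site -> uncalled -> quality -> adapter -> contaminant;
    each pair receives at most one discard reason, from the first failing
    filter. The adapter and contaminant screens run only when configured.
    """
    config = config or DemuxConfig()
    if isinstance(reads, tuple):
        reads = read_fastq_pairs(*reads)
    by_sample: dict[str, list[ReadRecord]] = {s: [] for s in sheet.barcodes}
    discards = {reason: 0 for reason in DISCARD_REASONS}
    n_input = 0
    for read in reads:
        n_input += 1
        if assign_barcode(read, sheet, config.max_barcode_mismatch) is None:
            discards[read.discard_reason] += 1
            continue
        passed = (
            check_cutsite(read, config.cutsite)
            and filter_uncalled(read)
            and filter_quality(read, config.window_frac, config.phred_floor)
            and (
                config.adapter is None
                or filter_adapter(read, config.adapter, config.adapter_max_mismatch)
            )
        )
        if passed and contaminant_index is not None and contaminant_index.is_contaminant(
            read, config.screen_min_hit_frac
        ):
            read.discard_reason = "contaminant"
            passed = False
        if not passed:
            read.assigned_sample = None  # a discarded read belongs to no sample bin
            discards[read.discard_reason] += 1
            continue
        by_sample[read.assigned_sample].append(read)
    return DemuxResult(by_sample=by_sample, discards=discards, n_input=n_input)
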