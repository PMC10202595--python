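"""Read-pair container and paired FASTQ input/output.

FASTQ is the standard 4-line, Phred+33 format; files ending in ``.gz`` are
transparently (de)compressed. The simulator annotates read titles with
``key=value`` tokens (insert length, truth locus/allele, duplicate and
contaminant flags); :func:`read_fastq_pairs` recovers them so that
downstream stages — insert-length deduplication and truth-based evaluation
— work from the files alone.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import FastqFormatError

#: discard categories recorded by the demultiplexer, in filter order
DISCARD_REASONS = (
    "no_barcode",
    "ambiguous_barcode",
    "no_cutsite",
    "uncalled_base",
    "low_quality",
    "adapter",
    "contaminant",
)


@dataclass
class ReadRecord:
    """One paired-end read: sequences, Phred+33 qualities and bookkeeping.

    ``insert`` is the sheared fragment length (barcode included); the
    simulator records it and real data would infer it from alignment.
    ``meta`` carries simulator truth tags when present. ``assigned_sample``
    and ``discard_reason`` are filled in by the demultiplexer; exactly one
    of them is set once filtering completes.
    """

    read_id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    insert: Optional[int] = None
    assigned_sample: Optional[str] = None
    discard_reason: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise FastqFormatError(
                f"read {self.read_id!r}: sequence/quality length mismatch"
            )

    def title(self) -> str:
        """FASTQ title line: id plus serialized key=value tokens."""
        tokens = [self.read_id]
        if self.insert is not None:
            tokens.append(f"ins={self.insert}")
        for key in ("smp", "loc", "al", "dup", "cont"):
            if key in self.meta:
                tokens.append(f"{key}={self.meta[key]}")
        return " ".join(tokens)

    @classmethod
    def from_titles(
        cls, title1: str, seq1: str, qual1: str, title2: str, seq2: str, qual2: str
    ) -> "ReadRecord":
        rid1, meta = _parse_title(title1)
        rid2, _ = _parse_title(title2)
        if rid1 != rid2:
            raise FastqFormatError(f"mate id mismatch: {rid1!r} vs {rid2!r}")
        insert = int(meta["ins"]) if "ins" in meta else None
        meta.pop("ins", None)
        return cls(rid1, seq1, seq2, qual1, qual2, insert=insert, meta=meta)


def _parse_title(title: str) -> tuple[str, dict]:
    parts = title.split()
    meta: dict = {}
    for token in parts[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    # strip a trailing /1 or /2 mate suffix if present
    rid = parts[0]
    if rid.endswith("/1") or rid.endswith("/2"):
        rid = rid[:-2]
    return rid, meta


def _open_text(path: Path | str, mode: str) -> IO[str]:
    path = Path(path)
    try:
        if path.suffix == ".gz":
            return gzip.open(path, mode + "t")
        return open(path, mode)
    except OSError as exc:
        raise FastqFormatError(f"cannot open {path}: {exc}") from exc


def write_fastq_pair(
    reads: Iterable[ReadRecord], r1_path: Path | str, r2_path: Path | str
) -> int:
    """Write read pairs to matched-order R1/R2 FASTQ files; returns pair count."""
    n = 0
    with _open_text(r1_path, "w") as f1, _open_text(r2_path, "w") as f2:
        for read in reads:
            title = read.title()
            f1.write(f"@{title}\n{read.seq1}\n+\n{read.qual1}\n")
            f2.write(f"@{title}\n{read.seq2}\n+\n{read.qual2}\n")
            n += 1
    return n


def read_fastq_pairs(r1_path: Path | str, r2_path: Path | str) -> Iterator[ReadRecord]:
    """Iterate read pairs from matched-order R1/R2 FASTQ files.

    Raises :class:`FastqFormatError` if the files hold different numbers of
    reads.
    """
    with _open_text(r1_path, "r") as f1, _open_text(r2_path, "r") as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise FastqFormatError(
                    f"mate-count mismatch between {r1_path} and {r2_path}"
                )
            yield ReadRecord.from_titles(*rec1, *rec2)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]
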