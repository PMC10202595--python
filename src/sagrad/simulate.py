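"""Synthetic SAG-RAD / bulk-RAD paired-end read simulator with known truth.

The simulator emulates a single-digest RAD library built from SbfI-digested
genomes of a diploid microeukaryote, amplified either from a single cell by
multiple displacement amplification (MDA; "sag" samples) or from bulk DNA
of a clonal culture ("bulk" samples):

* diploid multi-locus genomes across >=1 diverged populations, every
  haplotype beginning with the SbfI cut-site remnant ``TGCAGG`` (SbfI cuts
  CCTGCA^GG, so the barcode-adjacent read-through is TGCAGG);
* per-locus lognormal amplification factors (MDA branching bias acts at
  locus scale) shared by both alleles, plus allelic dropout — one allele of
  a heterozygous locus independently zeroed with probability
  ``dropout_prob``; bulk samples have unit weights and no dropout;
* library geometry: 7-bp inline barcodes, 150-bp paired reads, insert
  lengths from a normal centred on 400 bp clipped to [300, 600] (the shear
  target and the two size-selection bounds);
* contaminant read pairs drawn from an unrelated genome with no cut-site
  remnant, PCR duplicates (exact copies of an earlier pair, same insert),
  and uniform per-base substitution errors (Q37 base quality, Q12 at
  injected errors).

Every sample in a dataset is a sequencing library of one *individual*;
several samples may be clonal replicates of the same individual, which is
how replicate-sharing and SAG-vs-bulk comparisons are set up.

All randomness flows from ``SimConfig.seed`` through stage-local
``numpy.random.Generator`` streams, so identical configs give byte-identical
FASTQ output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from ._hamming import hamming
from .errors import ConfigValidationError, DegenerateSampleError
from .io import ReadRecord, revcomp, write_fastq_pair

#: read-through left at the start of every RAD fragment after SbfI digestion
CUTSITE_REMNANT = "TGCAGG"

_BASES = "ACGT"
_Q_GOOD = chr(37 + 33)  # Q37
_Q_ERR = chr(12 + 33)  # Q12


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    Fractions are probabilities in [0, 1]; lengths are in bp. ``seed`` is
    mandatory — there is no global-state randomness anywhere.
    """

    n_populations: int = 3
    n_individuals_per_pop: int = 4
    n_sag_replicates: int = 1  # single-cell (MDA) libraries per individual
    n_bulk_replicates: int = 0  # clonal bulk libraries per individual
    n_loci: int = 500
    locus_length: int = 600
    het_rate: float = 0.1
    divergence: float = 0.02
    mda_sigma: float = 1.0
    dropout_prob: float = 0.2
    contamination_frac: float = 0.05
    pcr_dup_rate: float = 0.1
    reads_per_sample: int = 12500
    read_length: int = 150
    insert_mean: int = 400
    insert_min: int = 300
    insert_max: int = 600
    barcode_length: int = 7
    seq_error_rate: float = 0.001
    contaminant_genome_length: int = 10000
    seed: Optional[int] = None

    def validate(self) -> None:
        fractions = {
            "het_rate": self.het_rate,
            "divergence": self.divergence,
            "dropout_prob": self.dropout_prob,
            "contamination_frac": self.contamination_frac,
            "pcr_dup_rate": self.pcr_dup_rate,
            "seq_error_rate": self.seq_error_rate,
        }
        for name, value in fractions.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigValidationError(f"{name}={value} must be in [0, 1]")
        if self.mda_sigma < 0:
            raise ConfigValidationError("mda_sigma must be >= 0")
        for name in (
            "n_populations",
            "n_individuals_per_pop",
            "n_loci",
            "reads_per_sample",
        ):
            if getattr(self, name) < 1:
                raise ConfigValidationError(f"{name} must be >= 1")
        if self.n_sag_replicates + self.n_bulk_replicates < 1:
            raise ConfigValidationError(
                "each individual needs at least one sag or bulk replicate"
            )
        if self.locus_length < self.read_length:
            raise ConfigValidationError("locus_length must be >= read_length")
        if self.insert_min < self.read_length:
            raise ConfigValidationError("insert_min must be >= read_length")
        if not (self.insert_min <= self.insert_mean <= self.insert_max):
            raise ConfigValidationError(
                "insert_mean must lie within [insert_min, insert_max]"
            )
        if self.barcode_length < 4:
            raise ConfigValidationError("barcode_length must be >= 4")
        if self.read_length <= self.barcode_length + len(CUTSITE_REMNANT):
            raise ConfigValidationError("read_length too short for barcode + remnant")
        if self.contaminant_genome_length < self.insert_max:
            raise ConfigValidationError(
                "contaminant_genome_length must be >= insert_max"
            )
        if self.seed is None:
            raise ConfigValidationError("seed is mandatory")

    @property
    def n_samples(self) -> int:
        return (
            self.n_populations
            * self.n_individuals_per_pop
            * (self.n_sag_replicates + self.n_bulk_replicates)
        )


@dataclass
class SampleInfo:
    sample_id: str
    individual: str
    population: str
    mode: str  # "sag" | "bulk"
    barcode: str


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``genotypes[ind][locus]`` is the diploid pair of haplotype strings (each
    beginning with the cut-site remnant); ``weights[sample]`` is the
    (n_loci, 2) amplification weight array, zero exactly where
    ``dropout[sample]`` flags an allelic-dropout event.
    """

    config: SimConfig
    individuals: list[str]
    individual_pop: dict[str, str]
    genotypes: dict[str, list[tuple[str, str]]]
    het: dict[str, np.ndarray]
    samples: list[SampleInfo]
    contaminant_genome: str
    weights: dict[str, np.ndarray] = field(default_factory=dict)
    dropout: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def barcode_sheet(self) -> dict[str, str]:
        return {s.sample_id: s.barcode for s in self.samples}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutate(seq: str, rng: np.random.Generator, prob: float, start: int) -> str:
    """Substitute each position >= start independently with probability prob."""
    if prob <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(seq) - start) < prob)[0] + start
    for pos in hits:
        old = _BASES.index(chars[pos])
        chars[pos] = _BASES[(old + 1 + rng.integers(0, 3)) % 4]
    return "".join(chars)


def make_barcodes(
    n: int, length: int, rng: np.random.Generator, min_dist: int = 3
) -> list[str]:
    """Greedily draw n distinct barcodes with pairwise Hamming >= min_dist."""
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise ConfigValidationError(
                f"cannot place {n} barcodes of length {length} "
                f"at pairwise distance >= {min_dist}"
            )
        cand = _random_seq(rng, length)
        if all(hamming(cand, b) >= min_dist for b in barcodes):
            barcodes.append(cand)
    return barcodes


def simulate_population(config: SimConfig) -> SimTruth:
    """Draw genomes: ancestral loci, population variants, individual genotypes.

    Ancestral locus sequences are uniform over {A,C,G,T} after the fixed
    remnant; each population substitutes sites (beyond the remnant) with
    probability ``divergence``; each individual is heterozygous at a
    ``het_rate`` fraction of loci, the two alleles differing by a single
    substitution private to that individual.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 0])
    rem = len(CUTSITE_REMNANT)

    ancestral = [
        CUTSITE_REMNANT + _random_seq(rng, config.locus_length - rem)
        for _ in range(config.n_loci)
    ]
    # Divergence as drift at shared polymorphic sites: each site beyond the
    # remnant is polymorphic with probability `divergence` (one derived base
    # per site, shared across populations); each population independently
    # fixes the ancestral or the derived allele at every polymorphic site.
    # Expected per-site difference between two populations = divergence / 2.
    pop_seqs: dict[str, list[str]] = {f"pop{p}": [] for p in range(config.n_populations)}
    for seq in ancestral:
        sites = np.nonzero(rng.random(len(seq) - rem) < config.divergence)[0] + rem
        derived = {
            int(pos): _BASES[
                (_BASES.index(seq[pos]) + 1 + int(rng.integers(0, 3))) % 4
            ]
            for pos in sites
        }
        for p in range(config.n_populations):
            carry = rng.random(len(sites)) < 0.5
            chars = list(seq)
            for pos, hit in zip(sites, carry):
                if hit:
                    chars[int(pos)] = derived[int(pos)]
            pop_seqs[f"pop{p}"].append("".join(chars))

    individuals: list[str] = []
    individual_pop: dict[str, str] = {}
    genotypes: dict[str, list[tuple[str, str]]] = {}
    het: dict[str, np.ndarray] = {}
    for p in range(config.n_populations):
        pop = f"pop{p}"
        for i in range(config.n_individuals_per_pop):
            ind = f"{pop}_i{i}"
            individuals.append(ind)
            individual_pop[ind] = pop
            # heterozygous substitutions land inside the sequenced read-1
            # window so that both alleles are observable after assembly
            window_end = config.read_length - config.barcode_length
            het_flags = rng.random(config.n_loci) < config.het_rate
            pairs: list[tuple[str, str]] = []
            for locus, base_seq in enumerate(pop_seqs[pop]):
                if het_flags[locus]:
                    pos = rem + int(rng.integers(0, window_end - rem))
                    old = _BASES.index(base_seq[pos])
                    new = _BASES[(old + 1 + int(rng.integers(0, 3))) % 4]
                    alt = base_seq[:pos] + new + base_seq[pos + 1 :]
                    pairs.append((base_seq, alt))
                else:
                    pairs.append((base_seq, base_seq))
            genotypes[ind] = pairs
            het[ind] = het_flags

    barcodes = make_barcodes(config.n_samples, config.barcode_length, rng)
    samples: list[SampleInfo] = []
    bc_iter = iter(barcodes)
    for ind in individuals:
        pop = individual_pop[ind]
        for r in range(config.n_sag_replicates):
            samples.append(SampleInfo(f"{ind}_sag{r}", ind, pop, "sag", next(bc_iter)))
        for r in range(config.n_bulk_replicates):
            samples.append(
                SampleInfo(f"{ind}_bulk{r}", ind, pop, "bulk", next(bc_iter))
            )

    contaminant = _random_seq(rng, config.contaminant_genome_length)
    return SimTruth(
        config=config,
        individuals=individuals,
        individual_pop=individual_pop,
        genotypes=genotypes,
        het=het,
        samples=samples,
        contaminant_genome=contaminant,
    )


def apply_mda_bias(truth: SimTruth, config: SimConfig) -> SimTruth:
    """Populate per-sample amplification weights and dropout flags.

    SAG samples draw one lognormal(0, mda_sigma) factor per locus, shared by
    both alleles; at heterozygous loci one allele is independently zeroed
    with probability ``dropout_prob``. Bulk samples get unit weights and no
    dropout (mda_sigma = 0, dropout_prob = 0 by construction).
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed), 1])
    L = config.n_loci
    for info in truth.samples:
        drop = np.zeros((L, 2), dtype=bool)
        if info.mode == "bulk":
            w = np.ones((L, 2), dtype=float)
        else:
            factors = (
                np.ones(L) if config.mda_sigma == 0
                else rng.lognormal(0.0, config.mda_sigma, size=L)
            )
            w = np.repeat(factors[:, None], 2, axis=1)
            if config.dropout_prob > 0:
                het_flags = truth.het[info.individual]
                hit = (rng.random(L) < config.dropout_prob) & het_flags
                side = rng.integers(0, 2, size=L)
                drop[hit, side[hit]] = True
                w[drop] = 0.0
        truth.weights[info.sample_id] = w
        truth.dropout[info.sample_id] = drop
    return truth


def _insert_sd(config: SimConfig) -> float:
    # sd placing >=99% of the normal mass inside [insert_min, insert_max]
    half = min(
        config.insert_mean - config.insert_min, config.insert_max - config.insert_mean
    )
    return half / 2.576 if half > 0 else 0.0


def generate_reads(
    truth: SimTruth, config: SimConfig
) -> dict[str, list[ReadRecord]]:
    """Generate ``reads_per_sample`` read pairs for every sample.

    Per pair, in order: with probability ``pcr_dup_rate`` the pair is an
    exact copy of a uniformly chosen earlier pair (same insert length);
    otherwise with probability ``contamination_frac`` it is drawn from the
    contaminant genome (barcoded but without cut-site remnant); otherwise a
    (locus, allele) is chosen proportional to amplification weights and the
    pair covers the two ends of a sheared fragment of the drawn insert
    length. Sequencing errors are substitutions at ``seq_error_rate`` per
    base with quality downgraded to Q12.
    """
    config.validate()
    if not truth.weights:
        raise ConfigValidationError("weights not populated; run apply_mda_bias first")
    rng = np.random.default_rng([int(config.seed), 2])
    Lr = config.read_length
    bl = config.barcode_length
    sd = _insert_sd(config)
    genome = truth.contaminant_genome
    out: dict[str, list[ReadRecord]] = {}

    for info in truth.samples:
        sid = info.sample_id
        w = truth.weights[sid].ravel()
        total = w.sum()
        if total <= 0:
            raise DegenerateSampleError(
                f"sample {sid!r} has an all-zero amplification weight vector"
            )
        p = w / total
        n = config.reads_per_sample
        genotype = truth.genotypes[info.individual]

        dup_u = rng.random(n)
        cont_u = rng.random(n)
        choice = rng.choice(2 * config.n_loci, size=n, p=p)
        if sd > 0:
            inserts = rng.normal(config.insert_mean, sd, size=n)
        else:
            inserts = np.full(n, float(config.insert_mean))
        inserts = np.clip(np.rint(inserts), config.insert_min, config.insert_max)
        inserts = inserts.astype(int)
        dup_src_u = rng.random(n)
        cont_pos = rng.integers(0, len(genome) - config.insert_max + 1, size=n)
        if config.seq_error_rate > 0:
            k_err1 = rng.binomial(Lr, config.seq_error_rate, size=n)
            k_err2 = rng.binomial(Lr, config.seq_error_rate, size=n)
        else:
            k_err1 = k_err2 = np.zeros(n, dtype=int)

        reads: list[ReadRecord] = []
        for i in range(n):
            rid = f"{sid}:{i}"
            if i > 0 and dup_u[i] < config.pcr_dup_rate:
                src = reads[int(dup_src_u[i] * i)]
                meta = dict(src.meta, dup=1)
                meta["smp"] = sid
                reads.append(
                    ReadRecord(
                        rid, src.seq1, src.seq2, src.qual1, src.qual2,
                        insert=src.insert, meta=meta,
                    )
                )
                continue
            ins = int(inserts[i])
            if cont_u[i] < config.contamination_frac:
                frag = info.barcode + genome[cont_pos[i] : cont_pos[i] + ins - bl]
                meta = {"smp": sid, "cont": 1, "dup": 0}
            else:
                locus, allele = divmod(int(choice[i]), 2)
                hap = genotype[locus][allele]
                frag = info.barcode + hap[: ins - bl]
                meta = {"smp": sid, "loc": locus, "al": allele, "dup": 0, "cont": 0}
            seq1, qual1 = _sequence_mate(frag[:Lr], int(k_err1[i]), rng)
            seq2, qual2 = _sequence_mate(revcomp(frag[-Lr:]), int(k_err2[i]), rng)
            reads.append(
                ReadRecord(rid, seq1, seq2, qual1, qual2, insert=len(frag), meta=meta)
            )
        out[sid] = reads
    return out


def _sequence_mate(
    template: str, n_errors: int, rng: np.random.Generator
) -> tuple[str, str]:
    """Apply substitution errors to a template; return (sequence, quality)."""
    if n_errors == 0:
        return template, _Q_GOOD * len(template)
    chars = list(template)
    qual = [_Q_GOOD] * len(template)
    # positions drawn without replacement: a base is never hit twice, so
    # error positions always differ from the template
    positions = rng.choice(len(template), size=n_errors, replace=False)
    offsets = rng.integers(0, 3, size=n_errors)
    for pos, off in zip(positions, offsets):
        old = _BASES.index(chars[pos])
        chars[pos] = _BASES[(old + 1 + int(off)) % 4]
        qual[pos] = _Q_ERR
    return "".join(chars), "".join(qual)


def simulate_dataset(config: SimConfig) -> tuple[SimTruth, dict[str, list[ReadRecord]]]:
    """Convenience: simulate genomes, apply amplification bias, generate reads."""
    truth = simulate_population(config)
    truth = apply_mda_bias(truth, config)
    reads = generate_reads(truth, config)
    return truth, reads


def write_fastq(
    reads_by_sample: dict[str, list[ReadRecord]],
    out_dir: Path | str,
    truth: Optional[SimTruth] = None,
    gzip_output: bool = False,
) -> dict[str, Path]:
    """Write pooled paired FASTQ plus a sample manifest (and truth, if given).

    Reads of all samples are concatenated in sample order into one multiplexed
    R1/R2 pair, as they would come off a sequencing lane before
    demultiplexing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    r1 = out_dir / f"reads.R1{suffix}"
    r2 = out_dir / f"reads.R2{suffix}"
    pooled = (read for sid in reads_by_sample for read in reads_by_sample[sid])
    write_fastq_pair(pooled, r1, r2)

    manifest = out_dir / "manifest.tsv"
    paths = {"r1": r1, "r2": r2, "manifest": manifest}
    truth_path = out_dir / "truth.jsonl" if truth is not None else None
    with open(manifest, "w") as fh:
        fh.write("sample_id\tbarcode\tpopulation\tindividual\tmode\ttruth_file\n")
        for sid in reads_by_sample:
            if truth is not None:
                info = truth.sample(sid)
                fh.write(
                    f"{sid}\t{info.barcode}\t{info.population}\t"
                    f"{info.individual}\t{info.mode}\t{truth_path.name}\n"
                )
            else:
                fh.write(f"{sid}\t.\t.\t.\t.\t.\n")
    if truth is not None:
        write_truth(truth, truth_path)
        paths["truth"] = truth_path
    return paths


def write_truth(truth: SimTruth, path: Path | str) -> None:
    """Serialize a SimTruth as versioned JSON lines."""
    with open(path, "w") as fh:
        fh.write(json.dumps({"format": "sagrad-truth", "version": 1}) + "\n")
        fh.write(json.dumps({"type": "config", **asdict(truth.config)}) + "\n")
        fh.write(
            json.dumps({"type": "contaminant", "seq": truth.contaminant_genome}) + "\n"
        )
        for ind in truth.individuals:
            fh.write(
                json.dumps(
                    {
                        "type": "individual",
                        "id": ind,
                        "population": truth.individual_pop[ind],
                        "het": truth.het[ind].astype(int).tolist(),
                        "genotypes": [list(pair) for pair in truth.genotypes[ind]],
                    }
                )
                + "\n"
            )
        for info in truth.samples:
            fh.write(
                json.dumps(
                    {
                        "type": "sample",
                        "id": info.sample_id,
                        "individual": info.individual,
                        "population": info.population,
                        "mode": info.mode,
                        "barcode": info.barcode,
                        "weights": truth.weights.get(info.sample_id, np.empty(0))
                        .tolist(),
                        "dropout": truth.dropout.get(
                            info.sample_id, np.empty(0, dtype=bool)
                        )
                        .astype(int)
                        .tolist(),
                    }
                )
                + "\n"
            )


def read_truth(path: Path | str) -> SimTruth:
    """Load a SimTruth written by :func:`write_truth`."""
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("format") != "sagrad-truth":
            raise ConfigValidationError(f"{path}: not a sagrad truth file")
        config = None
        contaminant = ""
        individuals: list[str] = []
        individual_pop: dict[str, str] = {}
        genotypes: dict[str, list[tuple[str, str]]] = {}
        het: dict[str, np.ndarray] = {}
        samples: list[SampleInfo] = []
        weights: dict[str, np.ndarray] = {}
        dropout: dict[str, np.ndarray] = {}
        for line in fh:
            rec = json.loads(line)
            kind = rec.pop("type")
            if kind == "config":
                config = SimConfig(**rec)
            elif kind == "contaminant":
                contaminant = rec["seq"]
            elif kind == "individual":
                individuals.append(rec["id"])
                individual_pop[rec["id"]] = rec["population"]
                genotypes[rec["id"]] = [tuple(p) for p in rec["genotypes"]]
                het[rec["id"]] = np.asarray(rec["het"], dtype=bool)
            elif kind == "sample":
                samples.append(
                    SampleInfo(
                        rec["id"], rec["individual"], rec["population"],
                        rec["mode"], rec["barcode"],
                    )
                )
                if rec["weights"]:
                    weights[rec["id"]] = np.asarray(rec["weights"], dtype=float)
                    dropout[rec["id"]] = np.asarray(rec["dropout"], dtype=bool)
    if config is None:
        raise ConfigValidationError(f"{path}: missing config record")
    return SimTruth(
        config=config,
        individuals=individuals,
        individual_pop=individual_pop,
        genotypes=genotypes,
        het=het,
        samples=samples,
        contaminant_genome=contaminant,
        weights=weights,
        dropout=dropout,
    )
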