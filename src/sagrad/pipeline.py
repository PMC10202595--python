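"""End-to-end orchestration: sim -> demux -> assemble -> qc -> coancestry.

A :class:`PipelineConfig` holds one nested section per stage plus a single
mandatory global seed; stage randomness is derived from (seed, stage index)
so any stage can be rerun in isolation and two runs with the same config
produce byte-identical outputs. Every run writes a JSON manifest listing
each artifact with its SHA-256 checksum and the parameter values in force.

All thresholds of the standard analysis (m=3, M=2, n=2, 10,000-locus sample
floor, mean+3SD coverage cap, >3-stack confounded rule, 1 barcode mismatch,
2 adapter mismatches) are config defaults, never hard-coded in the stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import assembly as asm
from . import demux as dmx
from . import qc as qcm
from .coancestry import (
    build_haplotype_matrix,
    cluster_coancestry,
    coancestry as paint_coancestry,
    score_recovery,
)
from .errors import ConfigValidationError, PipelineStageError, SagradError
from .io import write_fastq_pair
from .simulate import SimConfig, simulate_dataset, write_fastq

logger = logging.getLogger("sagrad")


@dataclass
class AssemblyParams:
    m: int = 3
    M: int = 2
    n: int = 2
    absorb_max_dist: int = 4
    dedup: bool = True


@dataclass
class DemuxParams:
    max_barcode_mismatch: int = 1
    window_frac: float = 0.15
    phred_floor: float = 10.0
    adapter: Optional[str] = None
    adapter_max_mismatch: int = 2
    screen_enabled: bool = True
    screen_k: int = 31
    screen_min_hit_frac: float = 0.5


@dataclass
class QCParams:
    min_loci: int = qcm.DEFAULT_MIN_LOCI


@dataclass
class CoancestryParams:
    k: Optional[int] = None  # defaults to the simulated number of populations


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str = "sagrad_run"
    verbosity: str = "info"
    sim: SimConfig = field(default_factory=SimConfig)
    demux: DemuxParams = field(default_factory=DemuxParams)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    qc: QCParams = field(default_factory=QCParams)
    coancestry: CoancestryParams = field(default_factory=CoancestryParams)

    def __post_init__(self) -> None:
        # the global seed fans out; the sim section never carries its own
        self.sim.seed = int(self.seed)
        self.sim.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTION_TYPES = {
    "sim": SimConfig,
    "demux": DemuxParams,
    "assembly": AssemblyParams,
    "qc": QCParams,
    "coancestry": CoancestryParams,
}


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated PipelineConfig from nested plain dictionaries.

    Unknown keys are rejected with their full key path.
    """
    if not isinstance(data, dict):
        raise ConfigValidationError("config root must be a mapping")
    known_top = {"seed", "out_dir", "verbosity", *_SECTION_TYPES}
    for key in data:
        if key not in known_top:
            raise ConfigValidationError(f"unknown config key: {key}")
    if "seed" not in data or data["seed"] is None:
        raise ConfigValidationError("seed: missing (seeds are mandatory)")
    kwargs: dict[str, Any] = {
        "seed": data["seed"],
        "out_dir": data.get("out_dir", "sagrad_run"),
        "verbosity": data.get("verbosity", "info"),
    }
    for section, cls in _SECTION_TYPES.items():
        payload = data.get(section, {}) or {}
        if not isinstance(payload, dict):
            raise ConfigValidationError(f"{section}: must be a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        for key in payload:
            if key not in valid:
                raise ConfigValidationError(f"{section}.{key}: unknown config key")
        if section == "sim":
            payload = dict(payload)
            payload.setdefault("seed", data["seed"])
        try:
            kwargs[section] = cls(**payload)
        except (TypeError, ValueError) as exc:
            raise ConfigValidationError(f"{section}: {exc}") from exc
    return PipelineConfig(**kwargs)


def validate_config(path: Path | str) -> PipelineConfig:
    """Parse and validate a YAML pipeline config file."""
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigValidationError(f"{path}: malformed YAML: {exc}") from exc
    try:
        return config_from_dict(data or {})
    except ConfigValidationError as exc:
        raise ConfigValidationError(f"{path}: {exc}") from exc


def tiny_preset(seed: int, out_dir: str = "sagrad_tiny") -> PipelineConfig:
    """A minutes-scale end-to-end preset: 3 demes x 3 individuals, 200 loci."""
    return config_from_dict(
        {
            "seed": seed,
            "out_dir": out_dir,
            "sim": {
                "n_populations": 3,
                "n_individuals_per_pop": 3,
                "n_loci": 200,
                "n_bulk_replicates": 1,
                "reads_per_sample": 5000,
                "mda_sigma": 1.0,
                "dropout_prob": 0.2,
                "het_rate": 0.1,
                "divergence": 0.02,
            },
            "qc": {"min_loci": 50},
        }
    )


@dataclass
class AnalysisResult:
    """In-memory result of the sim -> demux -> assemble -> match chain."""

    truth: Any
    demux_result: dmx.DemuxResult
    assemblies: dict[str, asm.SampleAssembly]
    catalog_all: asm.Catalog
    matches_all: dict[str, asm.MatchSet]
    catalog_bulk: Optional[asm.Catalog]
    matches_bulk: dict[str, asm.MatchSet]

    def retained_loci(self, sample_id: str) -> list:
        return self.assemblies[sample_id].retained_loci


def analyze(
    sim_config: SimConfig,
    demux_params: Optional[DemuxParams] = None,
    assembly_params: Optional[AssemblyParams] = None,
) -> AnalysisResult:
    """Run the analysis chain in memory, without touching the filesystem.

    Simulates a dataset, demultiplexes the pooled reads, assembles every
    sample, builds the all-sample catalog (and, when bulk replicates exist,
    the bulk-only catalog) and matches samples against both.
    """
    from .simulate import simulate_dataset

    dp = demux_params or DemuxParams()
    ap = assembly_params or AssemblyParams()
    truth, reads = simulate_dataset(sim_config)
    sheet = dmx.SampleSheet(truth.barcode_sheet())
    index = (
        dmx.KmerIndex([truth.contaminant_genome], k=dp.screen_k)
        if dp.screen_enabled
        else None
    )
    demux_config = dmx.DemuxConfig(
        max_barcode_mismatch=dp.max_barcode_mismatch,
        window_frac=dp.window_frac,
        phred_floor=dp.phred_floor,
        adapter=dp.adapter,
        adapter_max_mismatch=dp.adapter_max_mismatch,
        screen_k=dp.screen_k,
        screen_min_hit_frac=dp.screen_min_hit_frac,
    )
    pooled = (r for sid in reads for r in reads[sid])
    result = dmx.demultiplex(pooled, sheet, demux_config, index)
    assemblies = {
        sid: asm.assemble_sample(
            sample_reads,
            sample_id=sid,
            m=ap.m,
            M=ap.M,
            absorb_max_dist=ap.absorb_max_dist,
            dedup=ap.dedup,
        )
        for sid, sample_reads in result.by_sample.items()
    }
    retained = {
        sid: a.retained_loci for sid, a in assemblies.items() if a.retained_loci
    }
    catalog_all = asm.build_catalog(retained, n=ap.n)
    matches_all = {
        sid: asm.match_to_catalog(loci, catalog_all, sample_id=sid)
        for sid, loci in retained.items()
    }
    bulk_ids = {s.sample_id for s in truth.samples if s.mode == "bulk"}
    bulk_retained = {sid: retained[sid] for sid in bulk_ids if sid in retained}
    catalog_bulk = None
    matches_bulk: dict[str, asm.MatchSet] = {}
    if bulk_retained:
        catalog_bulk = asm.build_catalog(bulk_retained, n=ap.n)
        matches_bulk = {
            sid: asm.match_to_catalog(loci, catalog_bulk, sample_id=sid)
            for sid, loci in retained.items()
            if sid not in bulk_ids
        }
    return AnalysisResult(
        truth=truth,
        demux_result=result,
        assemblies=assemblies,
        catalog_all=catalog_all,
        matches_all=matches_all,
        catalog_bulk=catalog_bulk,
        matches_bulk=matches_bulk,
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    level = getattr(logging, config.verbosity.upper(), logging.INFO)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)

    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "stages": {},
        "artifacts": {},
    }

    def register(stage: str, name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(out)),
            "stage": stage,
            "sha256": _sha256(path),
        }

    # ---- stage 0: simulation -------------------------------------------
    stage = "sim"
    try:
        logger.info("sim: %d samples, %d loci", config.sim.n_samples, config.sim.n_loci)
        truth, reads = simulate_dataset(config.sim)
        sim_dir = out / "sim"
        paths = write_fastq(reads, sim_dir, truth=truth)
        sheet = dmx.SampleSheet(truth.barcode_sheet())
        sheet_path = sim_dir / "sample_sheet.tsv"
        sheet.to_tsv(sheet_path)
        for name, p in {**paths, "sample_sheet": sheet_path}.items():
            register(stage, f"sim.{name}", Path(p))
        manifest["stages"][stage] = {
            "n_samples": config.sim.n_samples,
            "n_read_pairs": sum(len(v) for v in reads.values()),
        }
    except SagradError as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage 1: demultiplex + filters --------------------------------
    stage = "demux"
    try:
        dp = config.demux
        index = None
        if dp.screen_enabled:
            index = dmx.KmerIndex([truth.contaminant_genome], k=dp.screen_k)
        demux_config = dmx.DemuxConfig(
            max_barcode_mismatch=dp.max_barcode_mismatch,
            window_frac=dp.window_frac,
            phred_floor=dp.phred_floor,
            adapter=dp.adapter,
            adapter_max_mismatch=dp.adapter_max_mismatch,
            screen_k=dp.screen_k,
            screen_min_hit_frac=dp.screen_min_hit_frac,
        )
        pooled = (r for sid in reads for r in reads[sid])
        result = dmx.demultiplex(pooled, sheet, demux_config, index)
        demux_dir = out / "demux"
        demux_dir.mkdir(exist_ok=True)
        acct_path = demux_dir / "discard_accounting.tsv"
        result.write_accounting(acct_path)
        register(stage, "demux.accounting", acct_path)
        for sid, sample_reads in result.by_sample.items():
            r1 = demux_dir / f"{sid}.R1.fastq"
            r2 = demux_dir / f"{sid}.R2.fastq"
            write_fastq_pair(sample_reads, r1, r2)
            register(stage, f"demux.{sid}.r1", r1)
            register(stage, f"demux.{sid}.r2", r2)
        manifest["stages"][stage] = result.accounting()
        logger.info("demux: %s", result.accounting())
    except SagradError as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage 2: assembly, catalogs, matching -------------------------
    stage = "assemble"
    try:
        ap = config.assembly
        asm_dir = out / "assembly"
        asm_dir.mkdir(exist_ok=True)
        assemblies: dict[str, asm.SampleAssembly] = {}
        for sid, sample_reads in result.by_sample.items():
            assemblies[sid] = asm.assemble_sample(
                sample_reads,
                sample_id=sid,
                m=ap.m,
                M=ap.M,
                absorb_max_dist=ap.absorb_max_dist,
                dedup=ap.dedup,
            )
            table = asm_dir / f"{sid}.loci.tsv"
            asm.write_locus_table(assemblies[sid].loci, table)
            register(stage, f"assembly.{sid}.loci", table)
        retained = {
            sid: a.retained_loci for sid, a in assemblies.items() if a.retained_loci
        }
        catalog_all = asm.build_catalog(retained, n=ap.n)
        asm.write_catalog(
            catalog_all, asm_dir / "catalog.fasta", asm_dir / "catalog.tsv"
        )
        register(stage, "assembly.catalog_fasta", asm_dir / "catalog.fasta")
        register(stage, "assembly.catalog_tsv", asm_dir / "catalog.tsv")
        matches_all: dict[str, asm.MatchSet] = {}
        for sid, loci in retained.items():
            matches_all[sid] = asm.match_to_catalog(loci, catalog_all, sample_id=sid)
            mpath = asm_dir / f"{sid}.matches.tsv"
            asm.write_match_table(matches_all[sid], mpath)
            register(stage, f"assembly.{sid}.matches", mpath)

        bulk_ids = [s.sample_id for s in truth.samples if s.mode == "bulk"]
        catalog_bulk = None
        matches_bulk: dict[str, asm.MatchSet] = {}
        bulk_retained = {sid: retained[sid] for sid in bulk_ids if sid in retained}
        if bulk_retained:
            catalog_bulk = asm.build_catalog(bulk_retained, n=ap.n)
            asm.write_catalog(
                catalog_bulk,
                asm_dir / "bulk_catalog.fasta",
                asm_dir / "bulk_catalog.tsv",
            )
            register(stage, "assembly.bulk_catalog_tsv", asm_dir / "bulk_catalog.tsv")
            for sid, loci in retained.items():
                if sid in bulk_ids:
                    continue
                matches_bulk[sid] = asm.match_to_catalog(
                    loci, catalog_bulk, sample_id=sid
                )
        manifest["stages"][stage] = {
            sid: {
                "reads_in": a.n_reads_in,
                "duplicates_removed": a.n_duplicates_removed,
                "loci": a.filter_result.n_input,
                "retained": a.filter_result.n_retained,
                "confounded": a.filter_result.n_confounded,
                "extreme_coverage": a.filter_result.n_extreme,
            }
            for sid, a in assemblies.items()
        }
        manifest["stages"][stage]["catalog_size"] = len(catalog_all)
    except SagradError as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage 3: QC metrics -------------------------------------------
    stage = "qc"
    try:
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        reports = []
        for sid, a in assemblies.items():
            reports.append(
                qcm.qc_report(
                    sid,
                    a.loci,
                    bulk_match=matches_bulk.get(sid),
                    bulk_catalog=catalog_bulk,
                    min_loci=config.qc.min_loci,
                )
            )
        kept, dropped = qcm.sample_dropout(reports, min_loci=config.qc.min_loci)
        qcm.write_qc_table(reports, qc_dir / "qc_report.tsv")
        qcm.write_lorenz_points(reports, qc_dir / "lorenz_points.tsv")
        register(stage, "qc.report", qc_dir / "qc_report.tsv")
        register(stage, "qc.lorenz", qc_dir / "lorenz_points.tsv")
        # replicate sharing per individual with >= 2 matched sag replicates
        for ind in truth.individuals:
            rep_ids = [
                s.sample_id
                for s in truth.samples
                if s.individual == ind and s.mode == "sag"
                and s.sample_id in matches_all and s.sample_id in kept
            ]
            if len(rep_ids) >= 2:
                table = qcm.sharing_table({r: matches_all[r] for r in rep_ids})
                spath = qc_dir / f"sharing.{ind}.tsv"
                qcm.write_sharing_table(table, spath)
                register(stage, f"qc.sharing.{ind}", spath)
        manifest["stages"][stage] = {"retained": kept, "excluded": dropped}
        logger.info("qc: retained %d samples, excluded %d", len(kept), len(dropped))
    except SagradError as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage 4: coancestry / population structure --------------------
    stage = "coancestry"
    try:
        co_dir = out / "coancestry"
        co_dir.mkdir(exist_ok=True)
        # one sag sample per individual, first replicate, among retained
        chosen: dict[str, asm.MatchSet] = {}
        for ind in truth.individuals:
            for s in truth.samples:
                if (
                    s.individual == ind and s.mode == "sag"
                    and s.sample_id in kept and s.sample_id in matches_all
                ):
                    chosen[ind] = matches_all[s.sample_id]
                    break
        manifest["stages"][stage] = {}
        if len(chosen) >= 2:
            hap = build_haplotype_matrix(
                chosen, catalog_all, populations=truth.individual_pop
            )
            mat = paint_coancestry(hap)
            k = config.coancestry.k or config.sim.n_populations
            cluster_coancestry(mat, k=min(k, len(mat.individuals)))
            mat.write_tsv(co_dir / "coancestry.tsv")
            register(stage, "coancestry.matrix", co_dir / "coancestry.tsv")
            labels_path = co_dir / "cluster_labels.tsv"
            with open(labels_path, "w") as fh:
                fh.write("individual\tpopulation\tcluster\n")
                for ind, lab in zip(mat.individuals, mat.labels):
                    fh.write(f"{ind}\t{truth.individual_pop[ind]}\t{lab}\n")
            register(stage, "coancestry.labels", labels_path)
            ari = score_recovery(
                list(mat.labels),
                [truth.individual_pop[i] for i in mat.individuals],
            )
            manifest["stages"][stage] = {
                "n_individuals": len(mat.individuals),
                "n_shared_loci": hap.n_loci,
                "adjusted_rand_index": ari,
            }
            logger.info("coancestry: ARI=%.3f over %d loci", ari, hap.n_loci)
        else:
            manifest["stages"][stage] = {
                "skipped": "fewer than 2 retained individuals with sag data"
            }
    except SagradError as exc:
        raise PipelineStageError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
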