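"""Demultiplexing: barcode assignment, read filters, contaminant screen."""

from __future__ import annotations

import itertools

import pytest

from sagrad import (
    ConfigValidationError,
    DemuxConfig,
    FastqFormatError,
    KmerIndex,
    ReadRecord,
    SampleSheet,
    assign_barcode,
    check_cutsite,
    demultiplex,
    filter_adapter,
    filter_quality,
    filter_uncalled,
    simulate_dataset,
    write_fastq_pair,
)
from sagrad._hamming import hamming

from _oracles import binom_count_ci, brute_adapter_hit

Q37 = chr(37 + 33)
TAIL = "TGCAGG" + "ACGT" * 36  # remnant + filler


def read_with_prefix(prefix: str, make_read) -> ReadRecord:
    return make_read((prefix + TAIL)[:150].ljust(150, "A"))


class TestSampleSheet:
    def test_empty_sheet_rejected(self):
        with pytest.raises(ConfigValidationError):
            SampleSheet({})

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ConfigValidationError):
            SampleSheet({"a": "AAAAAAA", "b": "AAAAAAA"})

    def test_close_barcodes_warn_but_load(self):
        with pytest.warns(UserWarning, match="Hamming"):
            sheet = SampleSheet({"a": "AAAAAAA", "b": "AAAAATT"})
        assert sheet.barcode_length == 7

    def test_tsv_roundtrip(self, tmp_path):
        sheet = SampleSheet({"s1": "AAAAAAA", "s2": "CCCCCCC"})
        sheet.to_tsv(tmp_path / "sheet.tsv")
        assert SampleSheet.from_tsv(tmp_path / "sheet.tsv").barcodes == sheet.barcodes


class TestAssignBarcode:
    SHEET = SampleSheet({"A": "AAAAA", "B": "CCCGG", "C": "GGTTT"})

    def test_exhaustive_against_brute_force_rule(self, make_read):
        """Every 5-bp prefix is assigned exactly as the stated rule demands."""
        for prefix in ("".join(p) for p in itertools.product("ACGT", repeat=5)):
            read = read_with_prefix(prefix, make_read)
            result = assign_barcode(read, self.SHEET, max_mismatch=1)
            dists = {s: hamming(prefix, b) for s, b in self.SHEET.barcodes.items()}
            close = [s for s, d in dists.items() if d <= 1]
            if len(close) == 1:
                assert result == close[0]
                assert read.assigned_sample == close[0]
                assert len(read.seq1) == 145  # barcode trimmed
            else:
                assert result is None
                expected = "ambiguous_barcode" if len(close) > 1 else "no_barcode"
                assert read.discard_reason == expected

    def test_one_mismatch_rescued_and_trimmed(self, make_read):
        read = read_with_prefix("AAAAT", make_read)
        assert assign_barcode(read, self.SHEET) == "A"
        assert read.seq1.startswith("TGCAGG")

    def test_equidistant_barcodes_ambiguous(self, make_read):
        with pytest.warns(UserWarning):
            sheet = SampleSheet({"x": "AAAAA", "y": "AATAA", "z": "CCCCC"})
        read = read_with_prefix("AACAA", make_read)
        assert assign_barcode(read, sheet) is None
        assert read.discard_reason == "ambiguous_barcode"


class TestReadFilters:
    def test_cutsite_exact_remnant_required(self, make_read):
        assert check_cutsite(make_read("TGCAGG" + "A" * 144))
        bad = make_read("TGCAGC" + "A" * 144)
        assert not check_cutsite(bad)
        assert bad.discard_reason == "no_cutsite"

    def test_uncalled_base_in_either_mate_fails(self, make_read):
        assert filter_uncalled(make_read("ACGT" * 10))
        assert not filter_uncalled(make_read("ACGT" * 10, seq2="ACNT" + "A" * 36))
        reads = [make_read("ACGT" * 10, read_id=f"r{i}") for i in range(10)]
        for i in (2, 5, 7):
            reads[i].seq1 = "N" + reads[i].seq1[1:]
        assert sum(not filter_uncalled(r) for r in reads) == 3

    def test_quality_window_rule(self, make_read):
        # 150-bp read, window = ceil(0.15 * 150) = 23 bases
        assert filter_quality(make_read("A" * 150, seq2="A" * 150))
        q_run = Q37 * 60 + chr(2 + 33) * 30 + Q37 * 60
        bad = make_read("A" * 150, seq2="A" * 150, qual1=q_run)
        assert not filter_quality(bad)
        assert bad.discard_reason == "low_quality"
        q_single = Q37 * 75 + chr(2 + 33) + Q37 * 74
        assert filter_quality(make_read("A" * 150, seq2="A" * 150, qual1=q_single))

    def test_malformed_quality_raises(self, make_read):
        read = make_read("A" * 10, seq2="A" * 10, qual1=chr(20) * 10)
        with pytest.raises(FastqFormatError):
            filter_quality(read)

    def test_adapter_examples(self, make_read):
        adapter = "AGATCGGAAGAGC"
        body = "C" * (150 - len(adapter))
        assert not filter_adapter(make_read(body + adapter, seq2="T" * 150), adapter)
        two_mm = "AGTTCGGAAGAGC"
        assert not filter_adapter(
            make_read("C" * 50 + two_mm + "C" * 87, seq2="T" * 150), adapter
        )
        three_mm = "AGTTCGGTACAGC"
        assert filter_adapter(
            make_read("C" * 50 + three_mm + "C" * 87, seq2="T" * 150), adapter
        )

    def test_adapter_against_brute_force_oracle(self, make_read):
        import numpy as np

        rng = np.random.default_rng(77)
        adapter = "AGATCGGAAGAGC"
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            if rng.random() < 0.5:  # plant a mutated adapter copy
                copy = list(adapter)
                for _ in range(rng.integers(0, 4)):
                    copy[rng.integers(0, len(copy))] = rng.choice(list("ACGT"))
                pos = rng.integers(0, 60 - 5)
                seq = (seq[:pos] + "".join(copy))[:60].ljust(60, "G")
            read = make_read(seq, seq2="T" * 60)
            expected = brute_adapter_hit(seq, adapter, 2) or brute_adapter_hit(
                "T" * 60, adapter, 2
            )
            assert filter_adapter(read, adapter, 2) == (not expected)


class TestContaminantScreen:
    def test_verbatim_reference_read_flagged(self, make_read):
        import numpy as np

        rng = np.random.default_rng(5)
        ref = "".join(rng.choice(list("ACGT"), size=2000))
        index = KmerIndex([ref], k=31)
        read = make_read(ref[100:250], seq2=ref[300:450])
        assert index.is_contaminant(read)

    def test_unrelated_read_kept(self, make_read):
        import numpy as np

        rng = np.random.default_rng(6)
        ref = "".join(rng.choice(list("ACGT"), size=10000))
        read_seq = "".join(rng.choice(list("ACGT"), size=150))
        index = KmerIndex([ref], k=31)
        assert not index.is_contaminant(make_read(read_seq, seq2=read_seq))

    def test_k_longer_than_read_rejected(self, make_read):
        index = KmerIndex(["A" * 200], k=31)
        with pytest.raises(ConfigValidationError):
            index.is_contaminant(make_read("ACGTACGT", seq2="ACGTACGT"))

    def test_empty_reference_rejected(self):
        with pytest.raises(ConfigValidationError):
            KmerIndex([], k=31)

    def test_flags_agree_with_truth_labels(self, sim_config):
        config = sim_config(
            n_loci=50, reads_per_sample=4000, contamination_frac=0.05, seed=21
        )
        truth, reads = simulate_dataset(config)
        sample_reads = next(iter(reads.values()))
        index = KmerIndex([truth.contaminant_genome], k=31)
        flagged = {r.read_id for r in sample_reads if index.is_contaminant(r)}
        truth_cont = {r.read_id for r in sample_reads if r.meta.get("cont") == 1}
        assert flagged == truth_cont
        lo, hi = binom_count_ci(len(sample_reads), config.contamination_frac)
        assert lo <= len(flagged) <= hi


class TestDemultiplex:
    def _fixture(self, make_read):
        """10 hand-built pairs: 2 bad barcode, 1 no cut site, 1 with N, 6 clean."""
        sheet = SampleSheet({"sA": "AAAAAAA", "sB": "CCCCCCC"})
        clean1 = ("AAAAAAA" + TAIL)[:150]
        clean2 = ("CCCCCCC" + TAIL)[:150]
        reads = [
            make_read(("GGGGGGG" + TAIL)[:150], read_id="bad_bc_1"),
            make_read(("TTTTTTT" + TAIL)[:150], read_id="bad_bc_2"),
            make_read(("AAAAAAA" + "TTTTTT" + "ACGT" * 35)[:150], read_id="no_cut"),
            make_read(clean1, seq2="NCGT" + "A" * 146, read_id="with_n"),
        ] + [
            make_read(clean1 if i % 2 else clean2, read_id=f"clean_{i}")
            for i in range(6)
        ]
        return sheet, reads

    def test_hand_fixture_accounting_exact(self, make_read):
        sheet, reads = self._fixture(make_read)
        result = demultiplex(iter(reads), sheet)
        acct = result.accounting()
        assert acct["no_barcode"] == 2
        assert acct["no_cutsite"] == 1
        assert acct["uncalled_base"] == 1
        assert acct["assigned"] == 6
        assert result.n_assigned + sum(result.discards.values()) == 10

    def test_zero_reads_give_zero_table(self):
        sheet = SampleSheet({"sA": "AAAAAAA"})
        result = demultiplex(iter([]), sheet)
        assert result.n_input == 0
        assert all(v == 0 for v in result.accounting().values())

    def test_simulated_reads_routed_to_truth_sample(self, sim_config):
        config = sim_config(
            n_populations=2, n_individuals_per_pop=2, reads_per_sample=800, seed=22
        )
        truth, reads = simulate_dataset(config)
        sheet = SampleSheet(truth.barcode_sheet())
        pooled = [r for v in reads.values() for r in v]
        result = demultiplex(iter(pooled), sheet)
        assert result.n_assigned + sum(result.discards.values()) == len(pooled)
        for sid, bin_reads in result.by_sample.items():
            assert len(bin_reads) == config.reads_per_sample
            assert all(r.meta["smp"] == sid for r in bin_reads)

    def test_conservation_with_all_noise_sources(self, sim_config):
        config = sim_config(
            n_populations=2,
            n_individuals_per_pop=2,
            contamination_frac=0.08,
            pcr_dup_rate=0.15,
            seq_error_rate=0.005,
            reads_per_sample=1000,
            seed=23,
        )
        truth, reads = simulate_dataset(config)
        sheet = SampleSheet(truth.barcode_sheet())
        index = KmerIndex([truth.contaminant_genome], k=31)
        pooled = [r for v in reads.values() for r in v]
        result = demultiplex(iter(pooled), sheet, DemuxConfig(), index)
        assert result.n_assigned + sum(result.discards.values()) == len(pooled)
        # discarded reads belong to no bin; assigned reads carry no reason
        for bin_reads in result.by_sample.values():
            assert all(r.discard_reason is None for r in bin_reads)

    def test_idempotent_on_demultiplexed_input(self, sim_config):
        config = sim_config(reads_per_sample=300, seed=24)
        truth, reads = simulate_dataset(config)
        sheet = SampleSheet(truth.barcode_sheet())
        pooled = [r for v in reads.values() for r in v]
        first = demultiplex(iter(pooled), sheet)
        sid = truth.sample_ids[0]
        before = [(r.seq1, r.seq2) for r in first.by_sample[sid]]
        passthrough = SampleSheet({sid: ""})
        second = demultiplex(iter(first.by_sample[sid]), passthrough)
        assert [(r.seq1, r.seq2) for r in second.by_sample[sid]] == before

    def test_mate_count_mismatch_raises(self, sim_config, tmp_path):
        config = sim_config(reads_per_sample=50, seed=25)
        _, reads = simulate_dataset(config)
        sample_reads = next(iter(reads.values()))
        write_fastq_pair(sample_reads, tmp_path / "a.R1.fastq", tmp_path / "scratch.fastq")
        write_fastq_pair(sample_reads[:-5], tmp_path / "b.R1.fastq", tmp_path / "a.R2.fastq")
        sheet = SampleSheet({"s": "AAAAAAA"})
        with pytest.raises(FastqFormatError):
            demultiplex((tmp_path / "a.R1.fastq", tmp_path / "a.R2.fastq"), sheet)
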