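"""Locus assembly: dedup, stacks, merging, filters, catalog, matching."""

from __future__ import annotations

import numpy as np
import pytest

from sagrad import (
    ConfigValidationError,
    SampleSheet,
    assemble_sample,
    absorb_secondary,
    build_catalog,
    build_stacks,
    dedup_pcr,
    demultiplex,
    filter_loci,
    match_to_catalog,
    merge_stacks,
    simulate_dataset,
)
from sagrad.assembly import Allele, Locus, Stack
from sagrad._hamming import components_within

from _oracles import brute_partition


def seqs_at(base: str, *edits: tuple[int, str]) -> str:
    chars = list(base)
    for pos, ch in edits:
        chars[pos] = ch
    return "".join(chars)


BASE = "TGCAGG" + "ACGT" * 10  # 46 bp toy locus sequence


class TestDedupPCR:
    def test_identical_pair_same_insert_collapses(self, make_read):
        reads = [make_read(BASE, read_id="a", insert=400),
                 make_read(BASE, read_id="b", insert=400)]
        kept, removed = dedup_pcr(reads)
        assert len(kept) == 1 and removed == 1

    def test_same_sequence_different_insert_kept(self, make_read):
        reads = [make_read(BASE, read_id="a", insert=400),
                 make_read(BASE, read_id="b", insert=410)]
        kept, removed = dedup_pcr(reads)
        assert len(kept) == 2 and removed == 0

    def test_missing_insert_rejected(self, make_read):
        with pytest.raises(ConfigValidationError):
            dedup_pcr([make_read(BASE, insert=None)])

    def test_simulated_duplicates_removed(self, sim_config):
        # low coverage per locus keeps coincidental insert collisions rare
        config = sim_config(n_loci=600, reads_per_sample=3000, pcr_dup_rate=0.2, seed=31)
        _, reads = simulate_dataset(config)
        sample_reads = next(iter(reads.values()))
        n_truth = sum(r.meta.get("dup") == 1 for r in sample_reads)
        _, removed = dedup_pcr(sample_reads)
        assert n_truth <= removed <= n_truth + 0.02 * len(sample_reads)


class TestBuildStacks:
    def test_identical_reads_form_one_stack(self, make_read):
        stacks, secondary = build_stacks(
            [make_read(BASE, read_id=f"r{i}") for i in range(10)], m=3
        )
        assert len(stacks) == 1 and stacks[0].depth == 10 and not secondary

    def test_below_depth_floor_is_secondary(self, make_read):
        stacks, secondary = build_stacks(
            [make_read(BASE, read_id=f"r{i}") for i in range(2)], m=3
        )
        assert not stacks and len(secondary) == 2

    def test_mixed_groups_split_by_threshold(self, make_read):
        other = seqs_at(BASE, (10, "T"))
        reads = [make_read(BASE, read_id=f"a{i}") for i in range(3)] + [
            make_read(other, read_id=f"b{i}") for i in range(2)
        ]
        stacks, secondary = build_stacks(reads, m=3)
        assert [s.consensus for s in stacks] == [BASE]
        assert len(secondary) == 2

    def test_unequal_lengths_rejected(self, make_read):
        with pytest.raises(ConfigValidationError):
            build_stacks([make_read(BASE), make_read(BASE + "A")])


class TestMergeStacks:
    def test_distance_one_merges_into_two_allele_locus(self):
        a, b = BASE, seqs_at(BASE, (8, "T"))
        loci = merge_stacks([Stack(a, 5), Stack(b, 3)], M=2)
        assert len(loci) == 1
        locus = loci[0]
        assert {al.seq for al in locus.alleles} == {a, b}
        assert locus.consensus == a  # deepest allele wins
        assert locus.snp_positions == [8]
        assert locus.total_depth == 8

    def test_distance_beyond_m_stays_separate(self):
        a = BASE
        b = seqs_at(BASE, (8, "T"), (9, "A"), (10, "G"))
        assert len(merge_stacks([Stack(a, 5), Stack(b, 5)], M=2)) == 2

    def test_transitive_chain_merges_three_stacks(self):
        a = BASE
        b = seqs_at(BASE, (8, "T"), (9, "A"))
        c = seqs_at(BASE, (8, "T"), (9, "A"), (12, "C"), (13, "A"))
        # d(a,b)=2, d(b,c)=2, d(a,c)=4: one locus by transitive closure
        loci = merge_stacks([Stack(a, 4), Stack(b, 3), Stack(c, 3)], M=2)
        assert len(loci) == 1 and loci[0].n_alleles == 3

    def test_consensus_tie_breaks_lexicographically(self):
        a, b = seqs_at(BASE, (8, "T")), BASE
        loci = merge_stacks([Stack(a, 5), Stack(b, 5)], M=2)
        assert loci[0].consensus == min(a, b)


class TestOracleEquivalence:
    """Threshold clustering agrees exactly with all-pairs + networkx components."""

    def _random_instances(self, n_instances: int):
        rng = np.random.default_rng(2024)
        for _ in range(n_instances):
            n = int(rng.integers(2, 51))
            base = "".join(rng.choice(list("ACGT"), size=20))
            seqs = set()
            while len(seqs) < n:
                chars = list(base)
                for _ in range(int(rng.integers(0, 6))):
                    chars[rng.integers(0, 20)] = rng.choice(list("ACGT"))
                seqs.add("".join(chars))
            yield sorted(seqs), int(rng.integers(1, 4))

    def test_components_match_brute_force(self):
        for seqs, max_dist in self._random_instances(120):
            labels = components_within(seqs, max_dist)
            ours = {}
            for idx, lab in enumerate(labels):
                ours.setdefault(lab, set()).add(idx)
            assert {frozenset(v) for v in ours.values()} == brute_partition(
                seqs, max_dist
            )

    def test_merge_and_catalog_respect_oracle_partitions(self):
        for seqs, max_dist in self._random_instances(40):
            expected = brute_partition(seqs, max_dist)
            loci = merge_stacks([Stack(s, 3) for s in seqs], M=max_dist)
            got = {
                frozenset(seqs.index(al.seq) for al in locus.alleles)
                for locus in loci
            }
            assert got == expected
            catalog = build_catalog(
                {"s1": [Locus(i, s, [Allele(s, 3)], 1) for i, s in enumerate(seqs)]},
                n=max_dist,
            )
            got_cat = {
                frozenset(seqs.index(a) for a in locus.alleles)
                for locus in catalog.loci
            }
            assert got_cat == expected


class TestAbsorbSecondary:
    def _locus(self):
        return merge_stacks([Stack(BASE, 5), Stack(seqs_at(BASE, (8, "T")), 3)], M=2)

    def test_identical_secondary_adds_depth(self, make_read):
        loci = self._locus()
        absorbed, dropped = absorb_secondary(loci, [make_read(BASE)], max_dist=4)
        assert (absorbed, dropped) == (1, 0)
        assert loci[0].total_depth == 9
        assert next(a for a in loci[0].alleles if a.seq == BASE).depth == 6

    def test_equidistant_secondary_dropped(self, make_read):
        loci = self._locus()
        # alleles differ only at position 8 (G vs T); a read carrying C there
        # is one mismatch from each allele: a tie, so the read is dropped
        tie = seqs_at(BASE, (8, "C"))
        absorbed, dropped = absorb_secondary(loci, [make_read(tie)], max_dist=4)
        assert (absorbed, dropped) == (0, 1)
        assert loci[0].total_depth == 8

    def test_far_secondary_dropped(self, make_read):
        loci = self._locus()
        far = seqs_at(BASE, (20, "C"), (21, "C"), (24, "C"), (25, "A"), (28, "C"))
        absorbed, dropped = absorb_secondary(loci, [make_read(far)], max_dist=4)
        assert (absorbed, dropped) == (0, 1)


class TestFilterLoci:
    @staticmethod
    def _loci(depths, n_stacks=1):
        return [
            Locus(i, BASE, [Allele(BASE, int(d))], n_stacks) for i, d in enumerate(depths)
        ]

    def test_mean_plus_3sd_spares_moderate_outlier(self):
        # depths {10,10,10,10,1000}: mean 208, SD 396, threshold 1396
        result = filter_loci(self._loci([10, 10, 10, 10, 1000]))
        assert result.n_extreme == 0 and result.n_retained == 5
        assert result.depth_threshold == pytest.approx(1396.0, abs=1e-9)

    def test_mean_plus_3sd_removes_extreme_locus(self):
        # depths {10 x 99, 500}: mean 14.9, SD 48.8, threshold 161.2
        result = filter_loci(self._loci([10] * 99 + [500]))
        assert result.n_extreme == 1 and result.n_retained == 99
        assert result.depth_threshold == pytest.approx(161.2, abs=0.2)

    def test_confounded_means_more_than_three_stacks(self):
        loci = self._loci([10, 10], n_stacks=4) + self._loci([10], n_stacks=3)
        result = filter_loci(loci)
        assert result.n_confounded == 2
        assert [locus.confounded for locus in loci] == [True, True, False]

    def test_single_locus_skips_extreme_filter_with_warning(self):
        with pytest.warns(UserWarning, match="SD undefined"):
            result = filter_loci(self._loci([10]))
        assert result.n_retained == 1


class TestCatalogAndMatching:
    def _locus(self, seq, locus_id=0, depth=10):
        return Locus(locus_id, seq, [Allele(seq, depth)], 1)

    def test_identical_consensus_merges(self):
        catalog = build_catalog(
            {"s1": [self._locus(BASE)], "s2": [self._locus(BASE)]}, n=2
        )
        assert len(catalog) == 1
        assert not catalog.loci[0].diploid  # one shared allele

    def test_distance_two_merges_distance_three_does_not(self):
        near = seqs_at(BASE, (8, "T"), (9, "A"))
        far = seqs_at(BASE, (8, "T"), (9, "A"), (10, "G"))
        assert len(build_catalog({"a": [self._locus(BASE)], "b": [self._locus(near)]}, n=2)) == 1
        assert len(build_catalog({"a": [self._locus(BASE)], "b": [self._locus(far)]}, n=2)) == 2

    def test_inconsistent_lengths_rejected(self):
        with pytest.raises(ConfigValidationError):
            build_catalog({"a": [self._locus(BASE)], "b": [self._locus(BASE + "AA")]})

    def test_match_unique_within_n(self):
        catalog = build_catalog({"bulk": [self._locus(BASE)]}, n=2)
        query = self._locus(seqs_at(BASE, (8, "T")), locus_id=7)
        mset = match_to_catalog([query], catalog, sample_id="sag")
        assert mset.matches[7].catalog_id == 0
        assert mset.matches[7].distance == 1

    def test_match_beyond_n_unmatched(self):
        catalog = build_catalog({"bulk": [self._locus(BASE)]}, n=2)
        query = self._locus(seqs_at(BASE, (8, "T"), (9, "A"), (10, "G")), locus_id=3)
        mset = match_to_catalog([query], catalog, sample_id="sag")
        assert mset.unmatched == [3] and not mset.matches

    def test_tied_match_ambiguous(self):
        left = seqs_at(BASE, (8, "T"), (9, "A"))
        right = seqs_at(BASE, (12, "C"), (13, "A"))
        catalog = build_catalog(
            {"bulk": [self._locus(left, 0), self._locus(right, 1)]}, n=2
        )
        assert len(catalog) == 2  # d(left, right) = 4: not merged
        mset = match_to_catalog([self._locus(BASE, 9)], catalog, sample_id="sag")
        assert mset.ambiguous == [9] and not mset.matches


class TestRecoveryFromSimulation:
    def test_ideal_conditions_recover_truth_loci_and_alleles(self, sim_config):
        config = sim_config(n_loci=200, reads_per_sample=5000, het_rate=0.15, seed=33)
        truth, reads = simulate_dataset(config)
        sheet = SampleSheet(truth.barcode_sheet())
        pooled = [r for v in reads.values() for r in v]
        bins = demultiplex(iter(pooled), sheet).by_sample
        info = truth.samples[0]
        result = assemble_sample(bins[info.sample_id], sample_id=info.sample_id)

        window = config.read_length - config.barcode_length
        truth_alleles = [
            {g[0][:window], g[1][:window]}
            for g in truth.genotypes[info.individual]
        ]
        recovered = 0
        for expected in truth_alleles:
            for locus in result.retained_loci:
                if {a.seq for a in locus.alleles} == expected:
                    recovered += 1
                    break
        assert recovered >= 0.99 * config.n_loci
        assert np.mean([l.total_depth for l in result.retained_loci]) >= 20

    def test_read_conservation_through_assembly(self, sim_config):
        config = sim_config(
            n_loci=100, reads_per_sample=2000, pcr_dup_rate=0.1,
            seq_error_rate=0.005, seed=34,
        )
        truth, reads = simulate_dataset(config)
        sheet = SampleSheet(truth.barcode_sheet())
        bins = demultiplex(iter([r for v in reads.values() for r in v]), sheet).by_sample
        sid = truth.sample_ids[0]
        a = assemble_sample(bins[sid], sample_id=sid)
        assert (
            a.n_reads_in
            == a.n_in_stacks
            + a.n_secondary_absorbed
            + a.n_secondary_dropped
            + a.n_duplicates_removed
        )
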