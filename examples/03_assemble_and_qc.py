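"""Assemble RAD loci de novo and compute per-sample quality metrics.

The assembly chain per sample: PCR-duplicate removal by (read-1, insert
length), exact-identity stacks (depth >= m=3), merging stacks within
Hamming distance M=2 into loci, absorbing low-depth secondary reads, and
the two locus filters (confounded: > 3 stacks; extreme coverage:
> mean + 3 SD). QC then reports locus counts, coverage uniformity (Gini)
and heterozygosity for a biased single-cell library vs its clonal bulk.
"""

from sagrad import SimConfig, gini, heterozygosity
from sagrad.pipeline import analyze

config = SimConfig(
    n_populations=1,
    n_individuals_per_pop=1,
    n_sag_replicates=1,
    n_bulk_replicates=1,
    n_loci=400,
    reads_per_sample=10000,  # 25x nominal coverage
    het_rate=0.1,
    mda_sigma=1.0,
    dropout_prob=0.2,
    pcr_dup_rate=0.1,
    contamination_frac=0.0,
    seq_error_rate=0.001,
    seed=31,
)
res = analyze(config)

for info in res.truth.samples:
    a = res.assemblies[info.sample_id]
    depths = [l.total_depth for l in a.retained_loci]
    print(f"{info.sample_id} ({info.mode}):")
    print(f"  reads in {a.n_reads_in}, PCR duplicates removed "
          f"{a.n_duplicates_removed}")
    print(f"  loci assembled {a.filter_result.n_input}, retained "
          f"{a.filter_result.n_retained} "
          f"(confounded {a.filter_result.n_confounded}, "
          f"extreme coverage {a.filter_result.n_extreme})")
    print(f"  mean depth {sum(depths) / len(depths):.1f}x, "
          f"Gini {gini(depths):.3f}, "
          f"heterozygosity {heterozygosity(a.retained_loci):.3f}")

print("\nThe single-cell library recovers fewer loci, less uniform coverage "
      "(higher Gini)\nand lower apparent heterozygosity than the bulk library "
      "of the same individual —\nthe three signatures of MDA amplification "
      "bias this toolkit quantifies.")
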