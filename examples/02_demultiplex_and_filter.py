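"""Demultiplex pooled reads by inline barcode and apply the read filters.

Reads are binned by their 7-bp barcode (one mismatch rescued when
unambiguous) and then pass, in order: intact SbfI cut-site check, uncalled
bases, sliding-window quality, and a k-mer contaminant screen. Each read
pair lands in exactly one bin — the accounting always sums to the input.
"""

from sagrad import KmerIndex, SampleSheet, SimConfig, demultiplex, simulate_dataset

config = SimConfig(
    n_populations=1,
    n_individuals_per_pop=2,
    n_loci=200,
    reads_per_sample=5000,
    mda_sigma=1.0,
    dropout_prob=0.2,
    contamination_frac=0.05,  # the protocol's observed contaminant share
    pcr_dup_rate=0.1,
    seq_error_rate=0.001,
    seed=21,
)
truth, reads = simulate_dataset(config)
pooled = [r for v in reads.values() for r in v]

sheet = SampleSheet(truth.barcode_sheet())
screen = KmerIndex([truth.contaminant_genome], k=31)
result = demultiplex(iter(pooled), sheet, contaminant_index=screen)

print("discard accounting:")
for category, count in result.accounting().items():
    print(f"  {category:>18}: {count}")

total = result.n_assigned + sum(result.discards.values())
print(f"\nconservation: assigned + discarded = {total} = input ({result.n_input})")
flagged = result.discards["no_cutsite"] + result.discards["contaminant"]
print(f"contaminant-attributable discards: {100 * flagged / result.n_input:.1f}% "
      "(cut-site check catches most, the k-mer screen the remainder —\n"
      "contaminant fragments carry a barcode but no TGCAGG remnant)")
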