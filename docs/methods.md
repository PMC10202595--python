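# Methods

This note documents the models behind `sagrad`, the parameters that
matter, what the simulator does and does not emulate, and the numerical
and design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## What is being modeled

Single-digest RADseq reduces a genome to the fragments adjacent to SbfI
restriction sites; sequencing many individuals at these shared loci yields
genome-wide genotypes for population genetics. Applying the protocol to a
single amplified genome (SAG) — one cell amplified by multiple
displacement amplification (MDA) before library preparation — removes the
need for culturing but introduces three artifacts that this package
simulates and measures: skewed per-locus coverage, allelic dropout (ADO),
and contamination. A clonal *bulk* library of the same genotype serves as
the low-bias reference.

## Simulator

### Genomes and populations

Each of `n_loci` ancestral locus sequences is uniform over {A,C,G,T}
after a fixed 6-bp prefix, the SbfI cut-site remnant `TGCAGG` (SbfI
recognizes CCTGCAGG and cleaves CCTGCA^GG, so TGCAGG is the
barcode-adjacent read-through; an exact-match check on it is the primary
gate against random-sheared contaminant fragments).

Population divergence is modeled as drift at shared polymorphic sites:
each site beyond the remnant is polymorphic with probability `divergence`
(one derived base per site, shared across populations), and each
population independently fixes the ancestral or the derived allele with
probability ½. The expected per-site difference between two populations is
therefore `divergence`/2, and — crucially for a de-novo pipeline — most
loci stay within the catalog merge radius across populations, as they do
for real conspecific populations whose differentiation is dominated by
shared standing variation rather than private fixed differences. An
alternative (independent per-population substitution at the same per-site
rate) concentrates too many fixed differences inside the 143-bp assembled
window and severs cross-population locus sharing almost completely at the
default parameters; the drift model is the package's deliberate choice.
`divergence = 0` degenerates to identical populations.

Each individual is heterozygous at a `het_rate` fraction of loci; the two
alleles differ by one substitution placed uniformly inside the sequenced
read-1 window (positions 6–142 at the default geometry). Placement inside
the window makes both alleles observable by assembly — the property all
dropout/heterozygosity estimates rest on; a SNP beyond the window would be
invisible by construction, confounding assembly loss with geometric loss.
Multi-SNP alleles are intentionally not simulated: one substitution keeps
allele pairs at Hamming distance 1 < M, guaranteeing assemblability.

### Amplification model

MDA branching bias is modeled at locus scale: each SAG sample draws one
amplification factor per locus, lognormal(0, `mda_sigma`), shared by both
alleles. At heterozygous loci one allele is independently zeroed with
probability `dropout_prob` (the dropout flag in the truth object is
equivalent to a zero weight). Bulk samples — clonal replicates of the same
simulated individual — have unit weights and no dropout. The lognormal is
a modeling choice, not a measured distribution: locus-scale multiplicative
branching is the simplest mechanism that reproduces the strongly concave
Lorenz curves seen in MDA libraries, and its single shape parameter σ maps
monotonically onto the Gini coefficient (σ = 0 is bulk-like).

### Library geometry and noise

Defaults follow the protocol this package evaluates: 7-bp inline barcodes
(generated per dataset with pairwise Hamming ≥ 3, so 1-mismatch rescue is
unambiguous), 150-bp paired reads, insert lengths drawn from a normal
centred on the 400-bp shear target with the SD chosen so ≥ 99% of mass
falls within the 300–600 bp size-selection bounds, then clipped to them.
Read-1 is barcode + the locus prefix starting at the remnant; read-2 is
the reverse complement of the fragment's far end. Contaminant pairs
(`contamination_frac`, default 0.05 — the share reported for carefully
washed single-cell isolates) come from an unrelated random genome: they
carry a barcode (contaminating DNA is adapter-ligated like everything
else) but no remnant. PCR duplicates (`pcr_dup_rate`) are exact copies of
a uniformly chosen earlier pair, including insert length and qualities.
Sequencing errors are uniform substitutions at `seq_error_rate` per base,
drawn without replacement within a read so an error position never reverts
to the template; base qualities are a constant Q37 with Q12 at error
positions — enough signal for the quality filter without pretending to be
an instrument profile.

All randomness flows from the mandatory `seed` through stage-local
`numpy.random.Generator` streams (`[seed, stage_index]`), so identical
configs give byte-identical FASTQ and any stage can be re-derived in
isolation.

## Demultiplexing and filters

Filter order is fixed — barcode → cut site → uncalled base → quality →
adapter → contaminant screen — and each read pair receives at most one
discard reason, from the first failing filter, so the accounting table
always sums to the input count. Choices on points the upstream tools leave
open:

- *Barcode rescue*: exact match wins; otherwise a unique barcode within
  one mismatch; ties discard as ambiguous. Trimming removes the corrected
  barcode and nothing else.
- *"Intact" cut site* means an exact TGCAGG match, zero mismatches.
- *Quality*: a read fails when any sliding window of 15% of the read
  length has mean Phred < 10 (the conventional default of this filter
  family); whole-read discard only, no trimming. Encoding is fixed to
  Phred+33.
- *Both mates* are subject to the uncalled/quality/adapter/contaminant
  filters; only read-1 carries barcode and cut site. This is an assumption
  — the alternative (read-1 only) is not exposed.
- *Contaminant screen*: a read pair is contaminant when ≥ 50% of its
  31-mers occur exactly (either strand) in a user-supplied contaminant
  reference. This is a deliberately simple, fully reproducible stand-in
  for taxonomic classification; it preserves the pipeline role
  (pre-assembly contaminant removal) without an external database. In
  simulation the cut-site gate already removes ~all contaminants; the
  screen catches residuals carrying a spurious remnant.

## Locus assembly

Per sample: PCR duplicates are removed first — among pairs sharing both
the read-1 sequence and the insert length, the first is kept. Note the
identifiable event is "same sequence, same insert": independent molecules
that happen to draw the same integer insert are indistinguishable from
amplification copies and are removed too, so measured duplicate fractions
sit slightly above the simulated rate at high per-locus coverage
(≈ C(r,2)/190 extra removals per locus at r reads per locus under the
default insert spread).

Stacks are exact-identity read groups; groups of depth ≥ m (default 3)
are primary, the remainder secondary. No sub-threshold mismatch collapsing
is attempted — M-merging handles sequencing variants, and adequacy is
demonstrated by the recovery tests rather than assumed. Primary stacks
within Hamming distance M (default 2) merge into loci by transitive
closure, which is deterministic and order-independent (the cost — rare
over-merging chains — is accepted for testability). A locus's alleles are
its member stacks; its consensus is the deepest allele, ties broken
lexicographically. Secondary reads are absorbed by the unique nearest
allele within distance 4 (ties or farther: dropped) before depths are
finalized; absorption distance and the inclusion of absorbed reads in
depth statistics are package choices, exposed as parameters.

Locus filters, computed per sample over all pre-filter loci: *confounded*
= more than three allele-forming stacks (repeats or amplification
artifacts; a diploid should produce at most a few), *extreme coverage* =
total depth > mean + 3 SD (population SD, ddof = 0). With fewer than two
loci the SD is undefined and the extreme filter is skipped with a warning.
Under ideal simulation the depth distribution is tight, so the 3-SD rule
clips ~0.1% of ordinary upper-tail loci — visible in the recovery tests as
the loss of 0–2 loci per 500.

The catalog merges loci across samples at consensus distance ≤ n (default
2), again by transitive closure; a catalog locus's allele set is the union
of member alleles, and it is *diploid* when that set has ≥ 2 sequences.
Matching a sample against a catalog requires a unique minimum-distance hit
within n (the merge distance doubles as the match radius); tied minima are
recorded as ambiguous and excluded from matched counts.

## QC metrics

- Locus count = distinct retained loci; samples with fewer than
  `min_loci` (default 10,000; "fewer than" is strict, 10,000 is kept) are
  excluded from downstream analysis.
- The Lorenz curve is taken over **loci** (cumulative read fraction vs
  cumulative locus fraction, depths ascending), and the Gini coefficient
  is 1 − 2 × trapezoidal area — exact for the piecewise-linear curve.
  Depths are post-absorption total depths of retained loci. All-zero
  depth vectors raise a named error.
- Depth histograms use decade-spaced bins 1–1000 with 10 sub-bins per
  decade; values outside the range are clipped into the terminal bins so
  counts conserve.
- Heterozygosity = fraction of retained loci with more than one allele.
- ADO rate = matched loci homozygous in the sample whose catalog locus is
  diploid, divided by **all** matched loci (the definition is followed
  literally; normalizing by diploid-catalog matches only is available as
  an off-by-default flag).
- Replicate sharing tabulates, per catalog locus, how many clonal
  replicates recovered it (by k and by exact subset).

## Coancestry

A desk-scale stand-in for chromosome-painting coancestry inference — the
semantics are preserved, the MCMC machinery is not. Over the catalog loci
matched by *every* individual: individual *i* at locus ℓ computes
d(i,j,ℓ) = the minimum Hamming distance between any allele of *i* and any
allele of *j*; the argmin set N receives 1/|N| each at entry (i,j). Each
(individual, locus) contributes exactly 1, so each row sums to the shared
locus count (in floating point, exact up to 1/|N| rounding). The
directional matrix is symmetrized as (C + Cᵀ)/2 for display and
clustering — the conventional choice — converted to dissimilarity
(max − value, zero diagonal), and clustered with average linkage;
cutting at k gives population labels, scored against truth with the
Adjusted Rand Index. All tie-breaks are deterministic (lexicographic
individual order), so clustering needs no seed.

## Pipeline

`run_all` executes sim → demux → assemble → qc → coancestry from one YAML
config with a single mandatory seed; unknown keys are rejected with their
key path. All analysis thresholds (m, M, n, barcode/adapter mismatches,
quality window, min_loci, the 3-SD rule's inputs) are config defaults,
not hard-coded. The manifest lists every artifact with a SHA-256 checksum
and contains no timestamps, so identical configs yield byte-identical
manifests. The bulk catalog (when bulk replicates exist) is built from
bulk samples only and drives concordance/ADO; the all-sample catalog
drives sharing and coancestry, with one SAG replicate per individual
entering the coancestry matrix.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so every check
completes in seconds to a couple of minutes while keeping binomial
confidence intervals tight enough to be meaningful: 150–2,000 loci,
20–25× nominal coverage, 1–12 individuals, 10-seed averages for
monotonicity claims (Gini vs σ, ADO vs dropout). The sample-exclusion
threshold is exercised at its real value (10,000) on constructed reports
and at reduced values in end-to-end runs, where simulated locus counts
are necessarily far below real-genome scale.

## What passing tests do and do not show

The simulator emulates the protocol's geometry and the artifact classes,
not real data: no indels or structural variation (substitution-only
distances throughout), no chimeric MDA products, no GC- or
motif-dependent amplification, no instrument quality profiles, uniform
base composition, exactly one SNP per heterozygous locus, and a
contaminant that is a single random genome rather than a community.
Recovery and parameter-estimation results therefore validate the
*pipeline logic* — accounting conservation, assembler correctness against
brute-force oracles, estimator consistency (ADO → h·d, heterozygosity →
h·(1−d)), qualitative orderings (Gini increasing in σ), and structure
recovery — not performance on real libraries, where gapped variation,
repeat families and classifier-grade contamination would dominate the
error budget.

## Known limitations

- Hamming-only comparisons: a single indel shifts every downstream base
  and splits a locus irrecoverably; real data would need gapped matching.
- Insert-length deduplication over-removes at high per-locus coverage
  (collision effect quantified above).
- The extreme-coverage filter assumes an overdispersed real-data depth
  distribution; on narrow simulated distributions it clips the ordinary
  3-SD tail.
- Transitive-closure merging can chain distinct loci through intermediate
  sequences; at realistic locus divergence this is rare but not
  impossible.
- The coancestry stand-in treats loci independently and has no model of
  phasing, missingness or uncertainty; it recovers block structure, not
  calibrated relatedness coefficients.
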