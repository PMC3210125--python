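# Methods

## Scope and data model

`ampdiv` analyses bidirectional, barcoded amplicon pyrosequencing of a small
panel of AMP precursor transcripts. The panel is 13 amplicons over 9 AMP
isotypes: longer or highly variable coding sequences are covered by two
partially overlapping amplicons, and results for one AMP are pooled across
its amplicons on a shared transcript coordinate frame. All coordinates are
1-based inclusive on the sense strand of the amplified transcript.

Each `ReferenceAmplicon` carries, besides its sequence (≤ 440 bp, the PCR
product cap imposed by ~250 bp read lengths): the covered cds span and
reading-frame offset; the precursor residue index of its first fully
covered codon (`cds_codon_start`) and its offset on the parent transcript
(`transcript_start`) — the two fields that let partial and overlapping
amplicons agree on codon indices; the precursor region annotation (signal /
mature / C-terminal, in amino-acid coordinates; the truncated defensin MGDt
has no C-terminal extension); the cysteine-array positions (8, or 12 for
mytimycin); and the gene-specific primers (IUPAC degeneracy allowed in
primers only, never in references).

The bundled demo panel is a **synthetic stand-in**: sequences are random
sense-strand codons (stop-free, with TGT/TGC at the cysteine positions) with
the published precursor/mature lengths and region layout. It exists so the
pipeline runs end-to-end without redistributing reference sequences; real
panels are supplied as a directory of `reference.fasta` + `amplicons.tsv` +
`barcodes.tsv` + `adaptors.json` (schema in `reference_model.py`).

## Barcode and fusion-primer design

Barcodes are 5-mers with no two identical adjacent bases ("no homopolymer"
is read in its strictest sense, which also guarantees distinctness in flow
space) and pairwise Hamming distance ≥ 2, so a single sequencing error
cannot convert one barcode into another. `generate_barcode_set` shuffles
the 4·3^(k−1) homopolymer-free candidates with a seeded RNG and selects
greedily; the result is a *maximal* set (no candidate can be added),
deterministic and order-stable per seed. The greedy maximum is reported on
capacity errors but is not a proven optimum; for k = 5, distance 2 it is
70–86 across seeds, comfortably above the 39 barcodes a 13-amplicon ×
3-sample design needs. Fusion primers are adaptor (19-mer) + barcode +
gene-specific primer, 5′→3′; the pair report estimates nearest-neighbor Tm
(advisory only — degenerate positions are collapsed to one expansion) and
the longest self-/cross-complementary run via longest-common-substring
against the reverse complement, a string proxy for dimer propensity, not a
thermodynamic model.

## Read simulator

The simulator emulates the input the pipeline expects, with ground truth:

* **Haplotype pools.** Variants are substitutions only (the analysis calls
  SNCs; indels exist solely as sequencing noise). Sites are restricted to
  the primer-free covered cds by default — variants under a primer are
  unobservable because reads carry the primer oligo there. In haplotypic
  mode each site rides its own whole-amplicon haplotype at its specified
  frequency (reference at the residue); independent mode applies sites
  per-read. The pipeline's simulated study plants, per amplicon, a common
  site set shared by all samples plus a small per-sample exclusive set
  (defaults: 3 common sites at 5/10/20%, 1–3 exclusive sites at 6–18%),
  mirroring the observed structure in which most genuine variation is
  shared across geographic samples.
* **Reads.** Each read is adaptor + barcode + primer + template, sense or
  antisense with probability ½, starting at the fusion-primer end (amplicon
  sequencing has no random fragmentation). Template length is drawn
  N(226, 40) truncated to [110, 420] — calibrated so demultiplexed,
  quality-trimmed reads average ≈ 226 bp on a full-length amplicon. A
  junk fraction (default 15%, 88% of it shorter than 70 bp) emulates the
  short/low-quality reads that trimming discards.
* **Errors and qualities.** Per-base error probabilities follow a linear
  position-decay weight with lognormal noise, normalised per read so the
  mean equals `substitution_rate` (default 0.004). The recorded quality is
  q = round(−10·log₁₀ e) clipped to [2, 40], and substitutions are injected
  with probability 10^(−q/10) of the *recorded* integer quality — so
  qualities and error rates are mutually consistent by construction
  (rounding bias ≈ 0.2% in probability space). Homopolymer indels are
  injected per maximal run with a per-run-length rate table, non-decreasing
  in run length (the hallmark 454 failure mode); insertions duplicate a run
  base, deletions remove one. The truth sidecar records every injected
  error with its amplicon coordinate, the emitting haplotype, direction and
  junk flag. Identical seeds give byte-identical FASTQ.

What the simulator does **not** emulate: flowgram (SFF) signal space, PCR
chimeras, strand-specific error biases, or per-position context effects
beyond homopolymer runs. Passing recovery tests therefore show the
pipeline's correctness under a faithful but simplified error process, not
performance on any particular real instrument run.

## Preprocessing

Demultiplexing matches each read's prefix against all known
(adaptor + barcode + primer) keys, on the read as given and on its reverse
complement, and assigns the unique best match; ties or misses go to the
unassigned bin. Budgets are per segment: barcode 0 mismatches by default
(the distance-2 design makes 1-mismatch tolerance ambiguous; it is
configurable), primer ≤ 2 mismatches with IUPAC-aware comparison, adaptor
≤ 2. The full prefix, including the gene-specific primer, is clipped:
variant positions under primers are unobservable anyway, and retaining
primer bases would otherwise dilute allele frequencies at those columns.

Quality trimming is the modified-Mott algorithm: per base score
`limit − 10^(−q/10)` (limit 0.05), keep the contiguous segment with maximal
sum. Ties break to the smallest end, then smallest start; the
implementation works on prefix sums so an exhaustive O(n²) oracle using the
same prefix sums agrees bit-for-bit. A fully low-quality read trims to
empty. Trimming precedes the length filter (default minimum 100 bp; the
70 bp observational threshold is available by flag).

## Mapping and pileup

Alignment is an affine-gap Gotoh semi-global DP (numba-accelerated; a pure
Python path is kept as fallback): the read aligns end-to-end, reference
overhangs are free — the right model for primer-anchored amplicon reads.
Scoring defaults: match +1, mismatch −2, gap open −3, gap extend −1 (a gap
of length k costs open + k·extend). Homopolymer gaps are deliberately *not*
discounted, keeping substitution calls conservative. Ties prefer
match/mismatch over deletion over insertion, giving deterministic,
left-packed gap placement. Reads under 80% identity are flagged
non-specific and excluded. Reverse reads are aligned as their reverse
complement and reported on the sense strand.

Pileup columns keep raw A/C/G/T counts and **quality-passing** counts: an
observation passes only if its base quality ≥ 20 *and* the mean quality in
a ±5-base window on the read ≥ 15. The window radius is a design choice
(the upstream tool's "surrounding bases" width is unpublished); it is a
parameter. Insertions are excluded from columns; deletions are tallied
separately and never produce SNCs. Average base coverage = total aligned
read bases / reference length.

## SNC calling, merging, ω and frequency

A column yields one candidate SNC per non-reference allele when
quality-passing depth ≥ 30 and allele frequency ≥ 3% (both on
quality-passing counts). An optional `max_freq` flag marks near-fixed
columns as `suspect_reference` — a fixed difference in every read more
likely reflects an error in the reference singleton than a variant — rather
than dropping them (off by default).

Within the cds, SNCs sharing a codon are merged into one codon change (the
alternate codon applies all grouped alternates simultaneously); multi-allelic
positions produce one merged change per alternate. Classification is by
virtual translation with an own standard-code table. Component SNCs are
retained for the positional substitution maps. Per AMP × sample:

* `snc_total` — genuine SNCs over the whole precursor transcript (flanks
  included), pooled across the AMP's amplicons by (transcript position,
  alternate);
* `snc_cds` = ns + syn merged codon changes;
* ω = ns / syn, undefined (reported `[ns]`) when syn = 0;
* frequency = snc_cds / covered codons (the per-nucleotide variant,
  snc_cds / 3·codons, is also emitted). The per-codon form is the headline
  because the published per-sample values equal merged-change counts over
  covered codon counts exactly (e.g. 27/100 = 0.27); the formula's stated
  "sequenced nucleotides" denominator does not reproduce those digits.

Report rounding is decimal half-up: ω to 1 d.p., frequencies to 2 d.p.;
unrounded values are retained.

Known discrepancy documented rather than resolved: the source study's text
gives one sample a total of 292 SNCs while its per-AMP table sums to 264 —
plausibly per-amplicon double counting in overlap regions. The pipeline
reports per-amplicon and per-AMP (pooled) totals separately so both
conventions are available.

## Diversity statistics

Read clusters are exact groups (same length, 100% identity) of
sense-oriented read sequences; a cluster is reference-identical when its
sequence occurs verbatim in the reference amplicon. Clusters covered ≥ 3×
are aligned to fix the frame and translated over their fully covered cds
codons (codons containing gaps render `X`; clusters not spanning the whole
covered cds are flagged partial). Identical peptides merge — silent
redundancy removed — and the count of distinct peptides is the headline
diversity statistic; the fraction with ≥ 1 SNC is computed over *clusters*
(the published phrasing is ambiguous between clusters and reads; the
cluster reading is implemented and noted here). Cysteine-array retention
checks that every covered array position still encodes cysteine.

`common_exclusive` partitions SNC keys (AMP, transcript position, alternate)
over any sample collection into common-to-all, single-sample-exclusive, and
shared-but-not-universal sets, with percent-common per sample; pairwise
contrasts (farmed vs native, injected vs not) are the same operation on
two-sample collections.

Variability grouping: one-way ANOVA (scipy) with AMP as factor and the
per-sample frequencies as replicates, α = 0.001; on rejection, all-pairs
Tukey HSD (statsmodels) at α = 0.05, followed by a greedy homogeneous-subset
partition — AMPs sorted by mean frequency, a subset grows while no pair
inside it is significant (a compact-letter-display-style construction; the
source's grouping algorithm is unstated). The grouping is invariant to
input order. All-equal inputs (zero within-group variance, equal means)
make the ANOVA undefined and are reported as a single group with the
undefined flag set.

## Bench math

Equimolar pooling: molecules/µl = C·10⁻⁹·N_A / (bp_w·bp), with
bp_w = 660 g/mol per base pair (dsDNA convention; the source leaves the
value unstated) — 3.07 ng/µl of a 400 bp amplicon ≈ 7·10⁹ molecules/µl,
the pooling target. Peptide properties: average-mass MW (reduced chains —
whether published weights assume oxidized cysteines is unstated); pI by
bisection of the Henderson–Hasselbalch net charge with EMBOSS pKa values by
default (Bjellqvist selectable); hydrophobicity ratio = % residues in
{A, C, F, I, L, M, V, W}. These definitional choices are configurable and
documented rather than asserted to reproduce any published digits.

## Numerical and testing choices

* Desk-scale problem sizes: recovery tests run three amplicons at ~500×
  (≈ 800–1200 reads each); pipeline tests use 100–300 reads per pool on
  panel subsets. The published study's read-level numbers (360k reads,
  3378× mean depth) require the deposited data and are out of scope.
* Parameter recovery is scored over the primer-free covered cds — the
  region where the generator can plant variants, and which bidirectional
  reads cover at full depth. Primer-shadowed amplicon tails reachable only
  by rare near-full-length reads sit at the bare 30× floor, where a single
  error read is 3.3% and the published thresholds intentionally provide no
  protection; calls there are still reported (they remain in `snc_total`).
* With only a handful of planted sites a 0.95 recall bound is vacuous
  (one miss of 15 sites is already 0.93), so recovery tests plant 24 sites.
* Oracles: translation is cross-checked against Biopython's translator;
  Mott trimming against an exhaustive segment scan; alignment scores
  against an independent full-matrix DP; barcode sets against exhaustive
  pairwise validation over all 1024 candidate 5-mers; mean/SD against a
  two-pass computation.
* Determinism: every stochastic component takes an explicit seed; a fixed
  seed yields byte-identical FASTQ and byte-identical report files.

## Limitations

Exact-identity clustering makes peptide-variant counts depth-sensitive: at
low coverage with realistic error rates few clusters reach 3×, so the demo
run's peptide counts are small; the statistic is meaningful at study-scale
depth. ω is a raw count ratio, not an opportunity-normalised dN/dS — values
above 1 suggest, but do not test for, positive selection. The caller does
not phase SNCs into haplotypes (read clusters serve that role) and does not
call indels. Tm and dimer checks are advisory string heuristics, not
thermodynamic predictions.
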