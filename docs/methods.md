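# Methods

This note documents the models and procedures implemented in `mirwoodnet`,
the choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Study design being emulated

Three xylem tissues — normal wood (NW), tension wood (TW) and opposite wood
(OW) — with three biological replicates each (samples NW1…OW3, nine in
total). Small-RNA libraries are sequenced per sample; an mRNA expression
matrix over the same nine samples provides the target-validation side; a TF
annotation, a gene→pathway map and qPCR Ct tables complete the inputs.

## Read processing

Cleaning applies, in order: 3′ adapter trimming (exact match of the first
8 adapter bases anywhere in the read — the generator controls the adapter,
so no mismatch tolerance is needed); discard if the trimmed insert is
shorter than 18 nt; discard if N bases exceed 10% of the insert; discard if
any of the last 3 bases has Phred Q < 20 (the "3′ end low quality" rule made
concrete; window size configurable). **Accounting convention:** *clean
reads* are everything surviving these filters; *total sRNA* is the 18–30 nt
subset that downstream stages use; the *mapping ratio* is mapped/total sRNA
× 100, rounded to two decimals. Collapsed unique tags are placed by exact
string matching on both genome strands (no mismatches, matching the
"no-mismatch alignment" convention); a multi-locus tag is counted once (per
read, not per placement) and survives masking if at least one locus is
outside every masked feature. Coordinates are 1-based inclusive internally;
BED input is converted from 0-based half-open on read.

## Novel miRNA discovery

Unexplained tags (not matching any reference mature exactly or with ≤ 2
terminal trims, supported by ≥ 2 reads, ≤ 4 genomic placements) are
evaluated by folding genomic windows around each locus: two windows
(downstream-extended `[tag_start, tag_end + ext]` and
upstream-extended `[tag_start − ext, tag_end]` on the tag strand) at graded
extents 30/50/80 nt. Folding is base-pair maximization (Nussinov) over
AU/GC/GU pairs with hairpin loops ≥ 3, with a deterministic traceback
(the 3′ base pairs its 5′-most optimal partner). Energy minimization was
deliberately replaced by pair maximization: it is parameter-free and exactly
checkable against exhaustive structure enumeration; an energy backend can be
slotted in behind the same `(seq) -> (structure, pairs)` contract.

A window is accepted as a pre-miRNA hairpin when

1. the mature duplex is near-complete — at least max(14, len−3) mature
   bases are paired;
2. at least 60% of mature bases are paired;
3. G:U wobbles are at most 25% of the mature pairs;
4. every mature-base partner lies on one side of the mature (the mature is
   one stem arm);
5. at most 2 pairs fold inside the innermost mature pair (a larger internal
   stem means a branched, non-hairpin path).

Rules 1, 3 and 5 are stricter than the minimal "≥14 paired, single loop"
formulation. Under pair maximization that minimal rule set accepts 6–10% of
*random* genomic windows (random RNA pairs densely when the objective is
count, leaning on G:U wobbles and asymmetric bulges), which would swamp
novel calls with background tags. The adopted rules were calibrated once on
random vs constructed stem-loops: ≤ 0.8% false acceptance per window at
essentially complete acceptance of genuine precursors. Tolerating up to two
pairs inside the terminal loop matters in the other direction: loops of real
(and simulated) precursors pick up incidental single pairs under
maximization, and a zero-tolerance rule rejects genuine hairpins.

Accepted candidates are assigned IDs `novel_1, novel_2, …` in genome
coordinate order. Known calls take precedence over novel ones. Families are
assigned by edit distance ≤ 3 (edlib) to reference matures, ties to the
lexicographically smallest family.

## Differential abundance

Normalized abundance = mapped read count / total mapped reads × 10⁶, no
pseudocount at this stage; the normalization is scale-exact. Contrasts are
tissue pairs; with n = 3 replicates per group the test is a two-sided Welch
t-test on log₂(x + 1); the fold change is computed on pseudocounted group
means, FC = (mean_a + 1)/(mean_b + 1). A miRNA is significant when
|FC| ≥ 2 *and* P ≤ 0.05 on the raw P value (mirroring the study's raw-P
threshold); BH q-values are reported alongside for transparency. When both
groups are exactly constant the t statistic is undefined; the implementation
resolves this limit to P = 0 for disjoint constants and P = 1 for equal
ones, which is what makes the zero-noise recovery test exact. The test is
pluggable; a count-based exact test could be substituted without touching
the surrounding stages.

## Target prediction

The expectation score of a miRNA:site duplex is the sum of per-position
penalties — mismatch 1.0, G:U 0.5, gap 2.0 — doubled at miRNA positions
2–13 (5′→3′). These constants follow the widely documented defaults of the
standard plant target server and are exposed in `ScoringScheme`. The scan
considers, at every transcript start, the gapless duplex and every
single-nucleotide-bulge variant (extra transcript base or unpaired miRNA
base) with the bulge never between positions 10 and 11; at most one bulge
per site. Sites scoring ≤ 3.0 are reported best-first; ties between
variants at one start resolve gapless-first, then ascending bulge position,
transcript bulge before miRNA bulge (penalties are multiples of 0.25, so
float ties are exact). The cleavage coordinate is the transcript base
opposite miRNA position 10 — for a gapless site starting at s with an L-nt
miRNA, s + L − 10, i.e. the cut lies between s+L−11 and s+L−10. The
vectorized prefix-sum scanner is re-checked hit-by-hit against explicit
alignment reconstruction, and in tests against a position-by-position
brute-force oracle.

## Network

A predicted pair is validated when Pearson r ≤ −0.8 and two-sided P ≤ 0.05
across the nine samples (t transform, n−2 df; |r| = 1 maps to P = 0 by
convention). Correlations pool all nine samples; zero-variance profiles are
skipped and recorded with NaN statistics. TF genes among the validated
targets seed the co-expression layer: TF→gene edges at |r| ≥ 0.8, P ≤ 0.05,
sign retained, no self-edges. The assembled graph is directed and typed
(miRNA → TF/gene "targets" edges carrying the correlation evidence;
TF → gene "coexpressed" edges), exported as SIF, GraphML and a node table.
Enrichment of the network genes against the expression background uses the
hypergeometric upper tail P(X ≥ k) with BH correction across pathways.

A calibration fact worth knowing: at n = 9 the raw-P threshold pair
(|r| ≥ 0.8, P ≤ 0.05) admits ~1% of null gene pairs. The miRNA-target layer
is protected by the complementarity requirement (chance expectation-≤3 hits
are vanishingly rare), so its precision is effectively set by the planted
truth; the TF co-expression layer, which screens every gene per TF, will
contain a corresponding share of chance edges whenever the background gene
count is large. That is a property of the published threshold itself, not of
this implementation; the BH q-values in the outputs let a user apply an
FDR-controlled cut instead.

## qPCR

2^−ΔΔCt with amplification efficiency fixed at 2.0 (an efficiency-corrected
variant is exposed). ΔCt is target − reference per sample and technical
replicate within a normalization group (one reference gene per assay group:
U6 for miRNA assays, Ubiquitin for gene assays); the calibrator ΔCt is the
mean over the calibrator tissue's samples. Technical replicates are averaged
on the linear scale; summaries report mean ± SE and log₂ fold-change.
Adding any constant to all Ct values of a sample leaves the result invariant.

## Synthetic data generator

The generator's defaults are the study conditions: 3 tissues × 3
replicates, 8 known + 12 novel miRNA loci, 39 planted miRNA–target pairs of
which 21 fall on TF genes (53.85%), 4-fold planted abundance effects,
20,000 reads per sample, a 2 × 60 kb genome.

- **Genome.** Random background sequence with non-overlapping embedded
  precursors (`mature + loop + reverse-complement arm` with up to 2
  non-re-pairable substitutions; the loop is drawn from {A, C} so it cannot
  self-pair) and decoy rRNA/tRNA/snRNA/snoRNA/repeat features for the
  masking stage. Strands are random. Because a randomly drawn mature can be
  self-complementary enough to fold out of register, each embedded precursor
  is verified against the discovery criteria in its genomic context and
  redrawn otherwise — mirroring the fact that annotated miRNAs are, by
  definition, loci that pass discovery criteria. Mature lengths are drawn
  around a 21-nt mode (with a 24-nt shoulder), 70% start with U, and the
  21-nt class gets twice the base abundance, reproducing the canonical
  plant-library length peak at the read level.
- **Abundance.** Per-tissue expected proportions (stored ×10⁶ as expected
  RPM) from log-normal bases (median 200, log-sd 0.5); novel miRNAs carry
  one 4-fold tissue effect each, balanced up/down across tissues; two known
  miRNAs are present only in OW to exercise the per-tissue set logic.
  Replicates add multiplicative noise with log₂-sd `noise_sd` (default
  0.25). Reads are drawn multinomially at the configured depth: mature +
  adapter + fill, plus background from decoy features, random loci and
  unmappable junk, plus controlled fractions of 3′-degraded, N-contaminated
  and short-insert reads so every cleaning filter does real work.
- **Expression.** Planted target genes are decreasing affine functions of
  their miRNA's per-sample abundance plus Gaussian noise scaled so the
  theoretical correlation is −`target_r`; each TF target gets 3 downstream
  co-expressed genes at |r| = `target_r` with random sign. `target_r`
  defaults to 0.95: the requirement that ≥ 90% of planted pairs reach an
  *empirical* r ≤ −0.8 at n = 9 fixes it — by the Fisher-z approximation a
  true r of 0.9 passes only ~82% of the time at n = 9, while 0.95 passes
  ~96% — and the tissue-clustered abundance design concentrates the
  empirical r further. With `noise_sd = 0` the planted correlations are
  exactly −1.
- **Pathways, transcripts, Ct.** One pathway is over-represented among
  network genes (60% membership vs 5% in the background). Transcripts are
  random sequence with the exact reverse complement of the miRNA planted in
  each target gene. Ct values follow Ct = a − b·log₂(x) with a = 35, b = 1
  and the references held constant, so 2^−ΔΔCt recovers planted fold-changes
  exactly at zero noise.
- **Determinism.** All randomness flows from per-stage
  `default_rng([seed, stage])` streams; a fixed config gives byte-identical
  FASTA/FASTQ/TSV/JSON outputs, which the acceptance suite verifies.

`cfg.zero_noise()` switches off replicate noise, expression noise,
background reads and read-quality nuisances while keeping all planted
structure; under it the full pipeline must reproduce the truth table
exactly (miRNA set, per-contrast DE sets, all 39 validated pairs), and the
test suite asserts exactly that.

**What the synthetic data does not emulate:** sequencing errors beyond 3′
quality decay (no substitutions or indels in the insert), isomiR length
heterogeneity, multi-mapping repeat families, overdispersion beyond
log-normal replicate noise, correlated gene modules in the background
expression, and real secondary-structure thermodynamics. Passing tests
demonstrate internal correctness and calibration of the implemented rules,
not that the rules would reproduce any specific published miRNA catalog from
deposited reads — headline counts from the real experiment depend on the
deposited libraries and external tool versions and are treated as generator
configuration (12 novel miRNAs, 39 pairs, 21 TF targets), not as assertions.

## Problem sizes used by tests and acceptance

The default suite runs the full pipeline on 9 × 20,000 reads with a 120 kb
genome and 200 genes (~1 min), the 25-seed edge-recovery protocol on the
expression layer with scans restricted to the novel miRNAs, a 2,000-draw
null for the DE type-I error, a 100,000-draw permutation null for the
Pearson P oracle, and a reduced determinism run (5,000 reads, 40 kb, 120
genes). These sizes were chosen to make every check statistically meaningful
while keeping the whole suite in a few minutes on one CPU.
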