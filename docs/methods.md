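# Methods

`tcrprofile` evaluates how faithfully RNA-seq recovers a T-cell receptor
(TCR) repertoire, by simulating repertoires of known composition, passing
them through explicit observation models of single-cell and bulk
transcriptome sequencing, and measuring what the downstream analysis
chain — consensus clonotype calling, fractional abundance quantification,
cross-platform comparison, detection-power analysis and expression
signatures — can recover.

## Identity model

A clonotype is a V-CDR3-J triple on one chain locus: the V gene(s) at the
gene level, the CDR3 junction (amino acids; nucleotides optional) and the
J gene.  A clone is a unique (α, β) clonotype pairing.  Allele suffixes
(`*01`) are always stripped.  Mouse TRAV carries N-paralog duplications
with identical coding sequence; members of a declared identical-sequence
pair merge into one group rendered `A/B` and are *not* counted as
ambiguous.  The shipped 17-pair table is a representative default for the
simulator and can be replaced via YAML for another reference.  Only
in-frame, stop-free (productive) junctions are analysed.

## Repertoire and observation models

**Repertoire profiles.** `expanded` places a head of dominant clones —
default head frequencies 13/89, 12/89, 6/89, 5/89, 3/89, 3/89 and four of
2/89 (top clone ≈ 14.6%), the clone census observed in the
tumour-infiltrating cells — over a geometric tail carrying the remaining
mass (ratio 0.98 by default; the true tail shape beyond the top clones is
unobserved, so this is a configurable choice).  `diverse` emulates the
non-expanded spleen pool: near-uniform frequencies with a maximum capped
at 1e-3 (the most enriched transcript seen in that pool); the default is
exactly uniform, with optional log-normal jitter (capped and
redistributed by water-filling).  `custom` takes an explicit head and
spreads any remaining mass uniformly.

**Single-cell capture.** Cells are drawn i.i.d. from clone frequencies
(multinomial; no birth-death dynamics — the question being modelled is
sampling, not clonal kinetics).  Each chain is detected independently with
a per-locus probability (defaults: α 0.69 / β 0.85 tumour-like, α 0.57 /
β 0.77 spleen-like — the measured per-cell call rates, which already
reflect the per-cell consensus typing step).  A detected locus is
biallelic at a configured rate (1–11% by tissue and locus); the second,
distinct allele is drawn from the repertoire's chain distribution.
Undetected cells are retained with empty calls.

**Bulk CDR3 reads.** The CDR3-informative read count is
Binomial(total_reads, fraction) with per-locus fractions 1e-5 (α) and
2e-5 (β) of total reads — so ~150M reads yield ~1500/~3000 CDR3 reads —
and reads are allocated to chain clonotypes multinomially.  A per-locus
fraction of reads receives an ambiguous V annotation (defaults α 0.23,
β 0.006, the 80-bp single-end rates; the true V is always among the N
candidates, N = 2 with probability 0.9 and 3 with 0.1 — the multiplicity
distribution is a choice, as only rates are reported).

**Caller emulation.** TCR-typing programs are emulated, not wrapped: each
of k callers independently drops each true clonotype (default 0.2), adds
Poisson-many spurious clonotypes (rate 0.05 × truth size) and widens V
sets with a homologous candidate (rate 0.05).  These defaults are
plausible for RNA-seq-tailored tools; truth labels ride along for
scoring.

## Consensus rule

A clonotype is retained when at least `min_agree` (default 2) callers
report the same CDR3 + J.  Agreement on V uses the largest caller subset
whose reported V-gene sets have a non-empty intersection (ties broken by
support, then caller id); an empty intersection is *no* match, because
irreconcilable V sets are different V-CDR3-J identities.  Within a
retained junction, each read-group's candidate V set is restricted to the
cross-caller intersection — so one caller's spurious widening is removed,
while ambiguity shared by every caller (the same underlying reads) is
reported as is.  Consensus support is the arithmetic mean of the agreeing
callers' supports (which caller's counts feed downstream abundance is not
otherwise determined; a designated-reference alternative would be equally
defensible).  Under independent dropout d, 2-of-3 consensus retains
1 − [d³ + 3d²(1−d)] of true clonotypes, which the simulation reproduces.

## Abundance

Transcript level: a read with N candidate V genes contributes 1/N of a
read to each candidate identity, conserving total weight at the read
count; `drop_ambiguous` discards N > 1 rows instead.  Clone level: cell
counts, where a biallelic cell contributes one count to each allele but
once to the denominator (cells with the chain, or with any chain, at the
clone level).  Percentages are reported at one decimal; ranking ties
break by descending weight then the lexicographic V|CDR3|J label.
Robustness to ambiguity is measured as Pearson r between frequency
vectors with and without ambiguous reads, over the union of clonotypes
with absentees as zero; zero variance raises an explicit error.

## Cross-platform comparison

Overlap between two abundance vectors uses the consensus identity rule
(identical CDR3 + J, non-empty V intersection) and reports unique-clonotype
counts (A-only / overlap / B-only) and the percentage of each side's read
weight carried by the overlap.  The detection ratio is 100·A/B on total
unique clonotypes, rounded to an integer — this arithmetic (bulk total
over targeted total) reproduces the published 14%/4% figures.  Top-k
concordance matches the k most abundant clonotypes per side and also
reports clonotypes shared overall but top-k on one side only.  V-J usage
is the joint V×J frequency (1/N per ambiguous candidate, or cell counts);
abundance spectra are clonotype counts per log10-frequency bin.

## Detection power

P(clone of frequency f seen in n cells) = 1 − (1−f)ⁿ; the minimal n for a
target probability is ⌈ln(1−p)/ln(1−f)⌉ with a boundary guard.  The joint
probability that every top-k clone is seen is computed exactly by
inclusion-exclusion (k ≤ 20) and by seeded Monte-Carlo with a standard
error.  "Sampling each top clone at least once" needs a probability
criterion that the source analysis leaves open; the default threshold in
the drivers is 0.5, exposed prominently as a user choice, and detection is
pre-dropout (an optional per-chain detection probability can scale f).

## Expression signatures

RPKM = 1e9·count/(length·total reads); cells with zero totals are
excluded.  Cell QC requires marker positivity (RPKM ≥ 1 for ≥ 1 of
Cd3d/g/e), ≥ 1M total reads, unique-exon ratio ≥ 0.5 and mitochondrial
fraction ≤ 0.25.  Differential expression between two groups: presence =
RPKM ≥ 1 per cell, genes absent from > 50% of the higher-expressing group
are excluded; fold change is the ratio of group mean RPKMs; p-values come
from a two-sided Student's t-test (pooled variance; Welch selectable) on
log2(RPKM + 1) — the pseudocount handles zeros and is configurable;
significance requires FC ≥ 1.5 or ≤ 1/1.5 *and* p ≤ 0.05 (the procedure's
significance direction is evidently p ≤ 0.05).  No multiple-testing
correction is applied, matching the evaluated procedure; BH-FDR is
available but off by default in the drivers.  The clone signature is the
direction-consistent intersection of exactly four comparisons, ranked by
mean fold change (down-regulated genes by mean reciprocal).  Because the
four comparisons share reference groups, null genes leak into the
intersection at roughly n_null·α² rather than the naive α⁴; the planted
design in the acceptance suite accounts for this.

## Synthetic data: what it does and does not show

The generator reproduces the *sampling structure* of the study — clone
frequency regimes, per-locus coverage, detection and biallelic rates,
ambiguity rates, caller disagreement, log-normal expression with planted
effects and planted QC failures.  It does not model V(D)J recombination
biology, nucleotide-level reads or sequencing error, UMI structure,
batch effects, or the true inter-program error correlations; passing
tests therefore demonstrate correctness of the analysis chain and
self-consistency of the stated sampling model, not the real-data values
(which require the original sequencing data).  Worked-example numbers
(clonal abundances, detection percentages, platform ratios) are
recomputed from the published census counts, which the package treats as
inputs.

## Problem sizes and numerics

Default experiment sizes keep every driver in seconds-to-a-minute:
consensus recovery pools 20 × 200 clonotypes; top-clone recovery pools
100 seeds × 92 cells; the platform contrast runs 100 seeded comparisons
over a 1000-clone expanded and an 80 000-clone diverse repertoire (~3000
bulk CDR3 reads each); the signature design uses 2050 genes × 164 cells.
The diverse-contrast condition (≤ 5 overlapping clonotypes in ≥ 95% of
runs) sits close to its own threshold under this model — the expected
overlap is ≈ 2.5–2.7 clonotypes, putting the per-run probability near
0.95 — so that check is the most seed-sensitive in the suite.  All
generators are bit-reproducible under a fixed seed; frequency vectors are
validated to sum to 1 within 1e-9; fractional weights use exact summation
(`math.fsum`) when conservation is asserted.
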