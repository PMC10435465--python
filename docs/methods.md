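# Methods

## The locus and what the pipeline computes

The extended casein locus is a high-density regulatory neighborhood: five
*Casein* genes expressed in mammary tissue and induced roughly four to
five orders of magnitude between the virgin state and day 10 of
lactation, two salivary genes (`Prr27`, `Fdcsp`), the dual-specificity
ancestral gene `Odam`, and ~20 candidate regulatory elements bound by
STAT5, of which four closely spaced modules between `Csn1s2b` and `Odam`
form a 10 kbp super-enhancer. The package reconstructs the analysis
stages used to dissect such a locus — element calling, super-enhancer
classification, contact-domain-validated multigene locus assembly, and
effect-size estimation across enhancer/promoter deletion genotypes — and
provides a synthetic generator so that every stage can be scored against
a known truth without any external data.

## Element calling

Coverage is consumed as fixed-bin tracks (25 bp bins). The enrichment
caller computes, per bin, the upper Poisson tail
`P(X >= k)` against `lambda = max(global mean, 10 kb local mean)`, applies
Benjamini–Hochberg across bins, merges significant bins (narrow mode:
gaps of at most one bin; broad mode, used for H3K27ac: gaps of up to ten
bins at a 10x relaxed level), drops peaks shorter than two bins, and
reports the summit as the midpoint of the maximum bin. This is a
deliberately transparent stand-in for MACS2: the scientific content of
the stage is the *filter* applied afterwards — an element is kept only if
it is supported by a peak in both STAT5 replicates (the union span of
each overlapping cross-replicate pair) and overlaps at least one H3K27ac
broad peak (merged across replicates; overlap of >= 1 bp, since no
coverage threshold is published). A caller whose per-bin model is
closed-form can be verified against an independent oracle in the tests,
which a black-box dependency could not.

Known limitation: with a local-background window of 10 kb, an enriched
block comparable in size to the window raises its own background and
becomes undetectable. This is a real property of local-lambda callers in
dense clusters; the generator therefore simulates transcription-factor
binding as punctate footprints (<= 300 bp), which is also what ChIP of a
sequence-specific factor looks like.

## GAS motifs

Canonical (`TTCNNNGAA`) and non-canonical (`TTCNNNNGAA`) interferon-
gamma-activated-sequence motifs are matched exactly, overlaps allowed,
forward strand only — both forms are reverse-complement symmetric, so a
forward scan is exhaustive (a property test asserts this). `N` in the
subject sequence never matches. PWM scoring is out of scope: the
biological readouts here concern presence/absence of intact GAS cores.

## Super-enhancer classification

Elements whose centre lies within 2.5 kb of a TSS are removed, the rest
are stitched at 12.5 kb (both the published ROSE defaults, exposed on the
CLI), and stitched regions are ranked by total background-subtracted
STAT5 signal (summed over constituents; a conservation test guards
against double counting). With rank and signal rescaled to the unit
square, the cutoff is the right endpoint of the last segment whose
discrete slope exceeds 1; that region and all higher-ranked regions are
super-enhancers. A perfectly linear curve (e.g. uniform signals) never
exceeds unit slope and yields none. The discrete rule is deterministic
and oracle-checkable on four-point inputs, unlike tangent fitting.
Ranking uses STAT5 signal because the super-enhancer here is delineated
by its STAT5-bound modules; H3K27ac serves only to gate elements.

## Complex loci

Induced genes are those with estimated fold > 2 (strict) and BH-adjusted
p < 0.05 between pregnancy day 6 and either lactation time point, over
protein-coding genes only. Maximal runs of consecutive induced coding
genes (non-coding genes are invisible to adjacency) become candidate
loci; contact-domain borders are then enforced: a border strictly inside
a two-gene locus discards it, larger loci are partitioned at each
interior border (a gene body straddling a border is dropped — assigning
it to either side would leave a border inside a fragment), fragments with
more than two genes are kept and shrunk to their member-gene span. Spans
are then extended to cover STAT5A elements lying wholly within the
intergenic interval between a terminal member gene and the nearest
outside coding gene; if the extension swallows a border, the flank
retracts to the outermost element on the locus side. Finally only loci
with at least three member genes are reported, with a machine-readable
history of every decision. Counts in the two-/three-gene rules refer to
member (induced) genes — the stitched objects are built from those.

The whole pipeline is property-tested against a brute-force reference on
randomized small genomes, for border containment, idempotence, and
monotonicity (removing a border can only return genes to surviving loci;
the locus *count* is not monotone, since a split can turn one long run
into two surviving fragments).

## Expression model and estimators

Size factors are DESeq-style median-of-ratios (rescaled to geometric mean
1; total-count fallback with a warning when no gene is positive in every
sample). The differential test is a negative-binomial Wald test: per-gene
method-of-moments dispersion `alpha = (s^2 - m) / m^2` pooled across the
two groups (floored at 1e-8, capped at 10), delta-method standard error
of the log ratio of pseudo-counted group means (pseudo-count 0.5, so that
mutants silenced by four orders of magnitude keep finite fold changes),
and a t reference with `n_a + n_b - 2` degrees of freedom — at the
study's group sizes (n = 3–5) the t reference keeps the null
type-I error essentially nominal (measured ~0.051 at level 0.05), where a
normal reference would be anticonservative. Genes with fewer than ten
reads in total are excluded before testing. DESeq2's shrinkage estimators
are intentionally not reproduced; the downstream interface consumes only
the threshold decisions and group means, and the installed DESeq2
implementation is used as an independent cross-check of the size-factor
computation in the test suite.

Readouts: `percent_reduction = 100 (1 - mutant/WT)` on normalized,
pseudo-counted means; linear `fold_change`; per-sample library fraction
for gene sets; and comparative-Ct quantification
(`relative = 2^-ddCt`, Gapdh-normalized, calibrated on the wild-type
group mean).

## The synthetic generator

The generator is the study's stand-in, not a tuning dial. Its defaults
encode the published conditions: a 400 kbp window hosting the 330 kbp
core locus; eight named genes plus flanking filler genes and one
non-coding gene; 20 truth elements of four classes (4 SE modules spanning
exactly 10 kbp, local enhancers, promoter elements, 4 CTCF sites), 12 of
which carry embedded GAS motifs (the `Csn2` promoter carries one
canonical and one non-canonical site within 150 bp of the TSS, `Csn3-E2`
carries two canonical sites); contact domains whose borders lie outside
the core locus, plus a variant with a border bisecting it between
`Csn1s2a` and `Csn1s2b`.

Sequence: random bases with the configured motifs written in and all
spurious GAS occurrences scrubbed, so the truth motif list equals an
exhaustive scan exactly. Coverage: Poisson bins over background 1.0 with
triangular footprints (STAT5 punctate, heights 20–50x by element class;
H3K27ac broad, element ± 500 bp, height 35x); replicates differ only in
counting noise. Counts: NB with shared dispersion 0.05 (per-replicate
CV ~22%, typical of bulk RNA-seq in inbred mice) and mean =
baseline x stage factor x genotype effect. Wild-type L1 baselines put the
five caseins at ~55% of a ~5M-read library (`Csn2` 1.2M expected counts);
casein stage factors span virgin 3e-4 to L10 10x, i.e. ~4.5 orders of
magnitude; `Odam` sits at a detection-floor level before lactation and
rises 3x from L1 to L10. Effects are multiplicative on means
("99.99% reduction" = effect 1e-4) and follow the published per-genotype
reductions; group sizes per scenario follow the published panels
(n = 3–5). qPCR: `Ct = base - log2(effect) + N(0, 0.15)` with constant
Gapdh and a non-detect ceiling of 40 cycles. Methylation: Beta-distributed
CpG betas (concentration 60) around state means — active mammary
promoters 0.05, the `Fdcsp` promoter 0.95 in mammary, casein promoters
0.90 in liver.

What the generator does **not** emulate: read-level artifacts (mapping,
duplication, GC bias), compositional coupling between genes in a library,
confounding batch factors (RUVSeq removal is out of scope), biological
variance differences between genotypes (exposed as the single dispersion
knob), and Hi-C matrix noise (domains are consumed as intervals).
Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated noise model, not robustness to artifacts the
model excludes.

## Problem sizes and numerical choices

The default locus is 16,000 coverage bins x 4 tracks and ~320 genes x
8–14 samples per scenario; a full `run-all` takes well under a minute on
one CPU, and the recovery suite evaluates each deletion scenario at ten
fixed seeds (1–10) and compares the median estimate with the configured
truth. Estimator caveat worth knowing: with the 0.5 pseudo-count, percent
reductions of genes with wild-type means below ~100 counts are biased
low by up to ~1 point; truth targets for such genes are set high enough
in means to keep the bias inside the test tolerances. Ties in
super-enhancer ranking are broken by genomic position for determinism;
all randomness flows from explicit integer seeds through separate named
streams per data type, so every artifact is byte-reproducible.
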