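# Methods

This note documents the statistical models, the simulator, the numerical
choices, and the limits of what the test suite demonstrates.

## Coordinates and formats

All coordinates are 0-based half-open (BED convention) end to end; any
1-based input must be converted at the boundary. Overlap means at least one
shared base; there is no reciprocal-fraction option. Strand is metadata and
never flips coordinates — a TSS position is assumed to be the strand-aware
start as provided by the catalog.

## Interaction scoring

The pipeline is: exact-duplicate removal (canonicalized end pairs,
including strands) → self-ligation filter (intra-chromosomal span < 4 kb
dropped; the 4 kb floor also truncates the simulator's contact-decay law,
so one constant serves both roles) → assignment of tag ends to merged
anchor peaks (a PET with an unanchored end, or both ends in one anchor,
is excluded but audited) → background model → per-pair test.

The candidate universe is every same-chromosome merged-anchor pair with
midpoint span in [4 kb, 2 Mb] (both bounds configurable). Using the full
windowed universe — rather than only pairs with at least one tag — keeps
the Benjamini–Hochberg denominator and the expectation normalization
data-independent, which is what makes the null calibration testable; at
the scales this package targets (≲10⁴ anchors) the universe fits easily in
memory. Interaction records are still materialized only for pairs with at
least one PET.

The expectation for pair (i, j) is `N · m_i · m_j · f(d_ij) / Z` with Z
normalizing the sum of expectations to the total assigned count N.
Two refinements to the marginals matter in practice:

- **Leave-one-out:** each pair's own count is subtracted from both
  marginals before taking the product. Otherwise a strong loop contributes
  its own tags to its anchors' marginals and, in sparse data, can absorb
  most of its count into its own expectation and mask itself.
- **Empirical-Bayes shrinkage:** the leave-one-out marginals are shrunk
  toward the mean via a moment-matched Gamma-Poisson posterior
  (`(m + m̄²/v) / (1 + m̄/v)`, v the super-Poisson excess variance across
  anchors). Raw marginals carry Poisson counting noise whose reciprocal
  bias makes the test slightly anti-conservative; the shrinkage removes
  that bias while preserving genuine anchor heterogeneity (the prior
  collapses to the mean only when the dispersion is consistent with pure
  counting noise).

The decay f is fitted from the pair table itself: counts pooled into
log-spaced span bins (10 per decade over [4 kb, 10 Mb]), converted to
per-bp densities, normalized, and made non-increasing by isotonic
regression weighted by bin counts; empty bins inherit the nearest
populated value to their left so the propensity is strictly positive.

The p-value is the exact randomized Poisson upper tail
`p = P(X > k) + U·P(X = k)`, with U drawn once per pair from a generator
keyed by the scoring seed. A plain survival-function tail is available
(`tail="sf"`), but a discrete tail cannot be uniform under the null — at
expectation ≈ 1 only ~2% of null pairs reach p ≤ 0.05 — and an
uncalibrated p-value makes the downstream FDR meaningless as a rate; the
randomized tail is the standard exactly-uniform construction for discrete
tests and is fully reproducible given the seed. The reported score is
1 − q (BH-adjusted p), so score ≥ 0.9 means FDR ≤ 0.1; score and PET-count
thresholds are both exposed because published loop sets are conventionally
filtered on both.

## Enhancers

Active enhancers are H3K27Ac peaks that do not overlap any TSS ± 2.5 kb
window. Stitching merges same-chromosome enhancers within 12.5 kb
(transitively; signal sums, interval is the hull). Super-enhancers are
flagged by the rank-curve tangent rule: sort by signal, rescale rank and
signal to [0, 1], cut at the first inter-point slope exceeding 1. These
are the standard conventions of the super-enhancer literature; both
distances are overridable. With all signals equal there is no elbow and
nothing is flagged (a warning is emitted).

## Docking-site discovery

"CTCF within 2.5 kb of the TSS" is read as *peak interval intersecting*
[TSS − 2500, TSS + 2500); a stricter summit-in-window mode is available
(`summit_mode=True`). The enhancer test applies to the interaction's
partner *anchor* (anchor-level loop representation), not to individual
tags. One call is emitted per (TSS, CTCF peak), but genes are counted once
in all tallies and Venn decompositions regardless of peak multiplicity.
Venn regions are computed on gene-id sets for 2 or 3 cell types; larger
families are refused (a table is the right output there).

## Motifs and conservation

Motif scanning takes a JASPAR-style count matrix; column probabilities use
a pseudocount of 0.01 × column sum, log-odds are against a uniform 0.25
background by default, and the relative score rescales log-odds to [0, 1]
between the matrix's attainable minimum and maximum (this makes the
relative score nearly invariant to the background choice). Both strands
are scanned at every offset; windows containing non-ACGT bases are skipped
with a warning. Per peak, the best hit is the maximal relative score with
ties broken leftmost-then-plus-strand. Conservation meta-profiles average
a per-base track over strand-oriented motif ± flank windows (flank 250 bp
by default — a presentation choice, not a statistic); bases missing from the track are counted as 0, mirroring
wiggle-track absence semantics. The package ships a *synthetic* CTCF-like
19-column matrix for simulations; real analyses should supply the actual
database matrix as input.

## 4C quantification

The unit is the primary restriction fragment. Blind fragments (no
secondary-cutter site strictly inside) are discarded; fragments
intersecting viewpoint ± 10 kb are masked (the exclusion radius is a
declared choice — standard 4C practice, not a published constant).
Normalization is reads-per-fragment-per-million-**sequenced**-reads: the
denominator is every mapped read of the replicate, including reads later
discarded by the blind/viewpoint filters, so the scale reflects library
depth rather than filter composition (a retained-reads denominator couples
the normalization to the very signal being perturbed and inflates
recovered contact ratios). Smoothing is a running mean over eligible
fragments' midpoints in a 6 kb window evaluated every 500 bp; grid points
with no eligible fragment emit nothing. Regions are quantified as the mean
rpm over eligible fragments assigned by midpoint (making the
quantification partition-like); a region with no eligible fragment is
reported missing, never zero. Condition comparison is a classical
two-sided pooled-variance Student's t test per region with significance at
p < 0.05 and no multiple-testing correction across regions (matching the
convention of reporting raw p-values with asterisks); a BH-adjusted column
is written alongside for transparency. Degenerate inputs: zero pooled
variance with equal means gives t = 0, p = 1; with unequal means the
comparison is flagged degenerate and reported p = 0. Replicate bands are
mean ± t₍(1+level)/2, n−1₎·sd/√n at 90% by default.

## The simulator

The generator's defaults encode the study conditions the analyses assume:
a locus-scale genome (3 chromosomes × 5 Mb, 72 genes in disjoint ~208 kb
territories standing in for miniature TADs), CTCF backbone peaks with
exponential spacing of mean 10 kb (about half constitutive, the rest
present per cell type with probability 0.6), 400 bp peak width, and for
each planted docking gene a constitutive CTCF peak 2 kb upstream of the
TSS. 75% of genes are docking genes; each draws a cell-type membership
pattern weighted toward single-cell-type specificity (20% per singleton,
8% per pair, 16% all three), mirroring the observation that most docking
genes are cell-type-specific with a small shared core. In each docking
cell type the gene receives a 3–7-constituent H3K27Ac cluster (constituent
widths 0.8–2.5 kb, gaps 3–10 kb, so stitching unifies it) placed 30 kb to
~90 kb from the TSS and at least 10 kb clear of it, with a CTCF peak at
its central constituent and a planted loop (Poisson mean 50 PETs) to the
docking peak. Active genes also get promoter H3K27Ac peaks (which the
promoter filter must remove) and occasional unlooped typical enhancers.

PET background follows the generative law: one end uniform in a random
anchor, partner at a distance drawn from a d⁻¹ density truncated to
[4 kb, chromosome length], redrawn while off-chromosome; 100 background
PETs per anchor, 10% exact duplicates injected, order shuffled. 4C
libraries use exponential fragment lengths (mean 4 kb), Bernoulli(0.15)
blind flags, expectations ∝ max(d, 4 kb)⁻¹ from the viewpoint times a 6×
enrichment over planted regions, times the deletion scale (0.4 by default)
at those regions in the deleted condition; 100,000 reads per replicate,
3 replicates, Poisson counts, uniform positions within fragments. The
restriction digest is drawn once per experiment and shared by both
conditions (it is a property of the genome); depth is calibrated on the
wild-type expectation so the deleted library genuinely loses reads where
contact is lost. Sequencing depths, PET rates and enrichment factors are
desk-scale choices — the source studies publish no depths for these
assays — selected so that planted effects are comfortably but not
trivially detectable; they are not fitted to any result.

Randomness: one root seed; every generator derives an independent
substream keyed by its own name (CRC of the name mixed into the seed
sequence), so adding a generator never perturbs existing outputs, and all
outputs are byte-deterministic given the seed.

What the simulator does *not* model: realistic nucleotide composition or
mappability, copy-number aberration, trans contacts, biological (super-
Poisson) replicate variability in 4C, TAD-boundary insulation beyond the
territory construction, and enhancers shared between genes. Passing tests
therefore demonstrate the correctness and calibration of the *analysis*
under the declared generative assumptions, not performance on real
libraries — in particular the 4C t test sees pure counting noise, so its
power here is an upper bound on what correlated biological replicates
would give.

## Known limitations

- The confidence score emulates the threshold semantics of published loop
  scores (range [0, 1], filtered at 0.9 with a PET minimum) but is its own
  declared statistic (1 − BH q of a randomized Poisson tail); numerical
  values of scores from other pipelines are not comparable.
- Inter-chromosomal PETs are counted in audits but not scored.
- The `run` subcommand orchestrates the simulated end-to-end analysis;
  externally supplied data is analysed through the per-stage subcommands.
- Active-TSS status is a threshold on a user-supplied expression column;
  no expression assay modelling is attempted.
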