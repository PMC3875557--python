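# Methods

## The system and the model

An RNA-binding protein recognizes a short motif (GCAU, extended form
UGCAU) carried by many mRNAs and mildly accelerates their turnover; an
AU-rich element (AUUUUA) in the 3′UTR may contribute. All effects of
interest are small — abundance, half-life and translational-efficiency
changes of ≤ 2-fold — so each stage of the pipeline is built around a
statistic that can resolve a small shift: replicate averaging with a
z-threshold for target calling, quartile means over hundreds of genes
for the abundance trend, regression on log counts for decay, a
genome-wide empirical rank for translational efficiency, and an
internally controlled two-allele design for the qPCR comparisons.

## Coordinate and counting conventions

Sequences are RNA over {A,C,G,U,N}; DNA input is transcribed T→U at
ingest. Coordinates are 0-based half-open, lengths in nucleotides. Only
the sense strand is scanned (mRNA-level analysis). Motif occurrences may
overlap (overlaps matter for AU-rich motifs); an occurrence belongs to
the region containing its start position; N never matches. Genes with no
UTR annotation get 200-nt flanks, shrunk to keep a non-empty ORF on
short transcripts. Motif density is occurrences per kb of the *whole*
transcript, both UTRs included.

## Target calling

Net enrichment is IP log2 ratio minus the matched RRM-deleted-control
log2 ratio, averaged over independent experiments (two by default).
The threshold is `mean + z·SD` with z = 1.65 and the *sample* SD
(n−1 denominator — the population parameters are estimated, and the
choice is conventional); the comparison is strict, so a degenerate
zero-variance input calls nothing. Ranking is by descending net ratio
with lexicographic tie-breaks for determinism.

Overlap between two target lists uses the hypergeometric upper tail
computed via log-gamma and a log-space sum, because published overlaps
of this kind reach p ~ 10⁻⁷⁴ and a naive sum underflows. The universe
size is an explicit required parameter: published analyses rarely state
it, so the caller must. The implementation is cross-checked in the tests
against exhaustive draw enumeration (N ≤ 12) and an exact
rational-arithmetic tail sum at (k=111, K=326, n=262, N=6000) — a
6000-gene universe being the natural order for the yeast transcriptome.

Binomial category enrichment (`P(X ≥ k)` at a stated background
frequency) is provided for annotation categories. Note that published
category p-values of this kind often come from unstated tools; the exact
binomial here gives 3.8×10⁻⁷ for 91/262 at background 0.213 and 0.012
for 29/91, and no attempt is made to reverse-engineer any other test.

## Quartile response

Genes are split into four density quartiles by rank, sizes by the
largest-remainder rule (first quartiles get the extra genes), Q4 the
densest, ties broken by gene id. The response summary is the arithmetic
mean log2 fold change per quartile with a seeded 1000-draw bootstrap
95% CI (the reduction behind published error bars of this kind is
rarely stated; a within-quartile gene bootstrap is the assumption-light
choice). The control motif CGUA run through the identical path provides
the negative control.

## Decay kinetics

Each course is target/reference qPCR quantities at 0, 2, 5, 10, 15 min;
normalization divides the per-timepoint ratio by its t=0 value (the
reference cancels scale drift between samples). The fit is ordinary
least squares of `ln r` on t with a free intercept: the t=0 point enters
as data rather than being forced through 1, which makes the estimate
robust to mis-scaling of the t=0 sample, and replicates are pooled into
one regression. Half-life is ln2/k; the 95% CI maps the slope's
t-interval through the monotone transform, and a residual-resampling
bootstrap is exposed as an alternative. A fitted k ≤ 0 is surfaced as a
flagged non-decaying result with an infinite half-life sentinel, never
clipped. On noise-free input the fit recovers the truth to machine
precision; on the simulated noise model the analytic CI covers the truth
at 95.8–97.8% across seeds (within the 92–98% band the tests assert).

## Translational efficiency

RPKM = count / (kb × million mapped reads), computed after removing
genes with fewer than 7 reads; gene length defaults to the ORF (full
transcript optional). TE is footprint RPKM over RNA RPKM; relative TE is
mutant over wild-type. The focal-gene test is empirical: exclude genes
whose raw count falls below 200 in *any* of the four libraries (the
strictest reading of a read floor), rank by descending relative TE with
ties sharing the better rank, and report p = rank/n_ranked. This
convention makes rank 1 of 500 give p = 0.002 and rank 19 of 9500 give
p = 0.002.

## Allele-ratio normalizations

The diploid carries a long and a short allele distinguishable by PCR,
one with intact motifs, the other with them mutated. The relative
abundance of an allele is the mean (median optional) long:short ratio
over replicate lanes within one genotype/configuration cell. Method 1
takes the motif-free allele's relative abundance in the wild-type
genotype divided by that in the deletion genotype; any motif-independent
effect of the mutations (the bias is real — published values put the
motif-free allele near 0.46 of its partner) cancels. Method 2 compares
the motif-bearing allele between genotypes, each lane normalized to the
motif-free partner, with a lane-resampling bootstrap CI. The genotype
effect is tested by a seeded two-sided permutation test on the group
mean difference (plus-one corrected; the pooled values are sorted and
split at the smaller group size, which makes the p-value exactly
invariant to swapping the group labels). A permutation test is used
rather than a t-test because lane ratios are ratio-scale and few.

## The synthetic-data generator

One global seed; every generator draws from its own deterministic
substream, so adding draws to one stage never perturbs another. Defaults
are the study conditions the pipeline is designed for:

* **Transcriptome** — 200 genes of 1–3 kb with 200-nt UTRs; motif
  densities evenly spanning 0–8 per kb, achieved by scrubbing
  spontaneous occurrences from a random background and planting the
  exact requested count (so realized density is exact, not approximate).
* **RIP-chip** — two independent experiments; planted targets (10% of
  genes) get a net shift of 3.0 log2 units; per-experiment net noise is
  Gaussian with SD 0.5, split evenly between IP and control channels.
* **Counts** — negative binomial (the standard overdispersed model for
  sequencing counts), dispersion 0.01 (deep technical-quality
  libraries), 2×10⁶ reads per library over a lognormal baseline
  (σ = 0.7); mutant RNA means scale as 2^(0.1 × density) (≈ 1.7-fold at
  the densest genes, matching the small published abundance effects);
  one focal gene carries a 1.53-fold TE multiplier in the mutant.
* **Decay** — first-order truth with multiplicative lognormal noise,
  CV 0.10, on both target and reference channels; wild-type half-life
  1.9 min.
* **Duplex** — 15 wild-type and 12 mutant lanes (the published
  replicate counts) in the Long-motif/Short-mutated configuration, which
  suffices for both normalization methods; band noise lognormal CV 0.2
  with a random per-lane scale (cancelling in every ratio);
  destabilization 1.5, allele bias 0.46.
* **Expression panel / structure tracks** — five-condition log2 panels
  with a density-proportional effect (positive in the mutant, negative
  in the over-expressor, Gaussian noise SD 0.3); structure tracks are a
  noisy flat baseline with a Gaussian dip (depth 1, σ = 5 nt) planted at
  motif centres of target genes.

What the generator does *not* emulate: array-level spatial artefacts and
loess normalization (inputs are assumed normalized), cell-cycle
confounding between the mutant and over-expressor strains, shut-off lag
after glucose addition, PCR saturation, correlated gene-gene expression
structure, and any coupling between RIP targets and motif density (the
generator plants them independently, so the screen-hit/target enrichment
is null by construction in the demo). Passing tests therefore show the
estimators are correct and calibrated under the stated noise models, not
that real data meet those models.

## Problem sizes

The test suite and the acceptance script run the simulation studies at
the sizes the analyses are designed around: 200 genes per transcriptome,
200 shut-off courses (median-recovery study), 500 courses (CI-coverage
study), 20 count simulations (TE recovery), 50 duplex simulations
(method-2 recovery), 10⁵ permutations for the genotype test. The whole
suite completes in a few seconds on one CPU.

## Known limitations

* The screen's published hit list includes rows admitted when they
  "nearly" met the criteria; the implementation is strict and exposes a
  `slack` parameter plus a per-clause audit instead of guessing the
  tolerance. Four bundled rows (GTO3, PDR15, ICT1, VTC3) fail the strict
  rule.
* The empirical TE p-value convention (rank/n) reproduces the published
  p = 0.002 only under that population's size; the ranked population is
  reported alongside p so the convention is transparent.
* The hypergeometric overlap magnitude depends on the (assumed) universe
  size; it is a required parameter everywhere.
* Half-life CIs assume homoscedastic log-scale noise; strongly
  heteroscedastic qPCR error would need weighting the regression.
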