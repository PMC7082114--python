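# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the simulators do and do not emulate,
and the numerical decisions that were genuinely open.

## Screen dropout model

sgRNA abundance at day 14 is compared with the initial plasmid pool, pair by
pair. TMM normalization follows the original trimmed-mean-of-M-values
recipe: M- and A-values over guides observed in both members, a double trim
(30% on M, 5% on A, rank-symmetric so that the two directions of a pair give
exactly reciprocal factors), and precision weights equal to the inverse
asymptotic binomial variance `(N_s−y)/(N_s y) + (N_r−y)/(N_r y)`. Guides with
a zero in either member are excluded from factor estimation but retained in
scoring. The pair's two factors are rescaled to multiply to one, as in
standard TMM implementations.

The per-guide log2 fold change is shrunken with a prior count *p* = 12
apportioned proportionally to effective library size (`y + p·L_j/L̄` over
`L_j + 2p·L_j/L̄`). This keeps zero counts finite, bounds the divergence of
low-count guides, and reduces exactly to the unshrunken ratio as counts grow.
The NB dispersion φ = 0.2 is part of the pipeline's fixed parameterization;
the point estimate itself does not depend on it.

Quantile normalization across cell lines uses the classic rank-based scheme
(target = across-column mean of sorted columns); ties receive the mean of the
target quantiles they span, which means tied columns are no longer exact
permutations of the target — an accepted property of tie averaging. Gene
scores are the first quartile of the guides' normalized scores, computed by
linear interpolation on (n−1) spacing (so scores 1..10 give 3.25). Q1 rather
than the median emphasizes the stronger half of the guides, appropriate when
a minority of guides per gene cut efficiently.

## Gene-level treatment contrast

For sensitizer/rescuer detection each gene is summarized per sample as the
median guide count (mean of central order statistics for even guide numbers,
so medians may be fractional). The NB generalized log-linear model with log
link and fixed φ = 0.2 is fitted by iteratively reweighted least squares,
batched across genes sharing a design; step halving enforces a non-increasing
deviance, convergence is a relative deviance change below 1e-8 (cap 100
iterations), and all-zero genes are fitted on 0.5-augmented responses. The
likelihood is evaluated with continuous gamma-function terms so fractional
medians need no re-rounding. Effective library sizes are recomputed from the
summarized matrix with TMM against the mean DMSO profile.

The gene-wise test of the treatment term is a likelihood-ratio test
(deviance difference against χ²(1)) — the canonical choice for nested NB
models with fixed dispersion. The volcano combines the mean of per-line
log2FC with the blocked joint model's p-value by default; a directional
Stouffer combination of per-line p-values is available as an alternative.
Where recovery analyses speak of a hit landing in the "extreme negative
tail" of the volcano, the tail is defined by the 1st-percentile mean-logFC
of genes without a planted treated-arm effect: a threshold on the null
distribution rather than a fixed share of all genes, so the count of true
hits cannot saturate it.
Type-I calibration of the LRT is checked on gene-level NB draws from the
model itself, not on median-of-guide summaries: the median of ten NB guides
is under-dispersed relative to NB(φ = 0.2), so a calibration check on
medians would measure the summarizer, not the fitter (on real medians the
fixed-φ test is conservative).

## Response signatures

Per-line treatment log2FC uses the same TMM + prior-shrinkage estimator as
the screen. Unreplicated treated/DMSO pairs are tested with the NB exact
test conditional on the gene's total (probability-mass two-sided rule,
enumerated exactly); replicated arms use the LRT. The
sensitive-vs-insensitive contrast Δ is the difference of group means of
per-line logFC with a Welch t-test per gene — the simplest statistic
consistent with comparing expression changes between line groups; moderated
alternatives can be substituted at the call site. Degenerate zero-variance
cases return p = 1 when Δ = 0 and the smallest positive float (flagged)
otherwise.

Threshold semantics follow the published cutoffs exactly and are covered by
boundary tests: target sets use strict `p < threshold` with inclusive
`|Δ| ≥ lfc`; both 0.68 and 0.7 log2 presets are shipped (the two cutoffs
used in the emulated analyses), with 0.68 the default for target-set work;
baseline DE uses inclusive `padj ≤ 10⁻¹⁰` and `|log2FC| ≥ 2` ("at least
4-fold"); overlaps use inclusive `padj ≤ 0.01` and the optional combination
filter `log2FC ≤ −log2 1.5`. Everything is collapsed to gene level;
transcript-level duality is out of scope.

PCA operates on log2(cpm+1) of the 2000 most variable genes, via SVD of the
gene-centered matrix with a deterministic sign convention (largest-magnitude
loading positive).

## Spike-in metagenes

The spike factor is `reference_spike_total / sample_spike_total`, applied
multiplicatively to experimental signal; any global rescaling of a track
cancels exactly, which is the property that makes genome-wide shifts of a
mark visible. The per-million style of spike scaling used by some protocols
differs only by a constant across samples and would not change any profile
shape or ratio. Windows are ±5 kb around the TSS in 50-bp bins (figure-level
choices, CLI-configurable); '−'-strand windows are the exact mirror image
`[tss−W+1, tss+W+1)`, reversed, making profiles invariant under reversing a
contig and flipping strands. Windows extending past a contig's covered
extent are dropped rather than padded, avoiding edge bias in the means.
Expression bins are quantile groups of log2(cpm+1) with stable tie-breaking;
matched control sets bin the pooled target∪universe expression into 20
quantile bins and sample controls per bin without replacement from a seeded
generator, flagging bins with insufficient depth as partial.

## Simulators: what they emulate and what they do not

All generators are pure functions of (config, seed) drawing NB counts with
variance μ + φμ² — the same family the analysis assumes, so recovery tests
measure the pipeline, not model mismatch. The screen plants 5% essentials
(−2 log2 in both arms), 2% sensitizers and 1% rescuers (∓1.5 log2, treated
arm only) on a 1000-gene, 10-guides-per-gene library across 4 cell lines
with 2 replicates per arm; guide-level efficacy jitter is N(0, 0.3) log2.
The expression panel has 5000 genes over 6 sensitive + 6 insensitive lines
(one DMSO and one treated sample each, as no replicate structure is part of
the emulated panel design), a 20-gene module suppressed by −1 log2 only in
treated sensitive lines, and 1% of genes with 8-fold baseline group shifts.
The module is planted among genes of above-median basal expression — the
transcriptional programs it stands in for (unfolded-protein-response and
translation genes in plasma-cell lines) are well expressed — which also
keeps the prior-count shrinkage of the recovered effect small (≈8% toward
zero at the panel's depth). Coverage tracks give each gene a triangular
2-kb TSS peak with amplitude ∝ log2(cpm+1), a spike contig carrying 5% of
total signal, per-sample depth scaling, and an optional global treatment
shrinkage (default 0.6) that only spike normalization can recover.

Not emulated: guide-specific off-target effects, copy-number artifacts,
transcript isoforms, batch structure, fragment-level coverage noise, or
peak shapes beyond the triangular kernel. Passing recovery tests therefore
demonstrates correctness of the estimators under the assumed NB/coverage
model, not robustness to those real-data complications.

## Statistical power at the panel's defaults

With unreplicated treated/DMSO pairs and NB dispersion φ = 0.1, a per-line
log2FC has standard deviation at least √(2φ)/ln 2 ≈ 0.65 regardless of
sequencing depth, so the 6-vs-6 Welch statistic for a −1 log2 module effect
has noncentrality ≈ 2.7 and per-gene power of only a few percent at
p < 10⁻³. The module is therefore recovered reliably in its *mean* contrast
(the 20-gene average carries ≈ 0.09 log2 of sampling noise; analyses average
over replicate panels where a tighter estimate is needed) while per-gene
membership calls at stringent p-cutoffs are power-limited by design of the
panel, not by the implementation. The analogous ceiling applies to baseline
DE at padj ≤ 10⁻¹⁰: only well-expressed planted genes clear it.

## Problem sizes

Defaults run the full pipeline in well under a minute on one CPU: the screen
is 10,000 guides × 17 samples, the panel 5000 genes × 24 samples, coverage
200 genes × 2 tracks; calibration checks use 2000 genes and 20 replicates.
These sizes were chosen so that Monte-Carlo error is small relative to every
tested margin while the whole suite stays interactive.

## Known limitations

Fixed common dispersion everywhere (no empirical-Bayes moderation); the
volcano's blocked model assumes a shared treatment effect across lines; the
exact test enumerates the full conditional support and is meant for
desk-scale totals; spike scaling assumes the spike fraction is constant
across samples of an experiment; matched control sampling can be partial
when the universe is thin in some expression bin.
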