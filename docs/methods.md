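# Methods

## Overview

`chipcompare` treats a ChIP experiment as one latent per-base enrichment
signal observed through two imperfect channels: a tiling two-channel
microarray (ChIP-chip) and short-read sequencing against an input-DNA
background (ChIP-seq). Everything downstream — profile construction,
signal-to-noise statistics, peak calling, TSS/TES meta-profiles — applies
the *same* criteria to both channels so that differences between the results
reflect the technologies, not the analysis. The synthetic-data module closes
the loop: it draws both observations from one planted signal, so each
pipeline stage can be validated against known ground truth.

## Profile construction

Coordinates are 0-based half-open throughout; bin *i* of width *b* covers
[*ib*, (*i*+1)*b*) and its centre is the coordinate *x_i* associated with the
bin. The working resolution is *b* = 50 bp; the last, possibly partial, bin
of each chromosome is always present.

**Reads.** 5′ positions are optionally shifted by a constant toward the
fragment midpoint (default `frag_len // 2`; the sign is a plain user
parameter, because conventions in the literature describe the shift both as
"toward the 5′ end" and toward the fragment centre, and only the
toward-the-midpoint direction aligns the two strands' count tracks — a
property the test suite verifies on simulated data). Shifted 5′ positions
are counted per bin; totals are conserved per chromosome.

**Probes.** Probe intensities are averaged per bin by probe midpoint; bins
containing no probe are masked out and stay masked through every later
stage.

**Smoothing.** Both channels are smoothed with a Nadaraya–Watson-normalized
Gaussian kernel, bandwidth 50 bp, truncated to the 400 nearest bins
(200 per side; one-sided at chromosome ends, skipping masked bins). The
normalization makes the operator linear and constant-preserving, which the
tests rely on. An unnormalized, literally transcribed kernel variant
`exp(+Δx²/50)` exists behind `printed_kernel=True` for comparison only; it
grows with distance and is not usable for analysis.

**Enrichment.** After smoothing, the per-bin enrichment is
`log2((IP+c)/s_IP) − log2((INPUT+c)/s_IN)`. For count tracks the scaling
totals `s` are the genome-wide sums (library-size normalization) and the
pseudocount is `c = 0.5`; for intensity tracks `s = 1` and `c = 0`
(intensities are strictly positive). Library-size scaling centres the
genome-wide mean enrichment near zero, which matches the peak caller's
per-chromosome centring assumption. Base 2 is used for all logarithms; the
choice affects scale only, never ranks or test decisions. Input libraries
are profiled as `log2(INPUT + c)` with the identical smoothing and
aggregation, since an input has no meaningful within-library ratio.

**Aggregation.** Twenty adjacent 50 bp bins are averaged (masked-in children
only; a parent is masked out only when all children are) to produce the 1 kb
profiles used for genome-wide statistics: skewness, correlations, GC
correlation, and peak calling in the input-swap experiment. The 50 bp
profiles feed TSS/TES meta-profiles and the planted-region recovery
benchmark, where sub-kilobase features matter.

**Variability masking.** Given ≥ 2 input profiles, bins whose across-input
SD exceeds the 0.95 quantile of the genome-wide SD distribution are masked
out; this mask is AND-combined with the probe mask before reproducibility
statistics, mirroring the exclusion of probe-free and unstable-input
regions.

## Signal-to-noise: truncated skewness

The skewness of a profile's enrichment distribution,
`m3 / m2^(3/2)` with 1/n central moments, is computed after removing the
lowest and highest 5 % of values by rank (⌊n·trim⌋ values per tail). A
positive value means a long right tail — genuine enrichment standing out of
roughly symmetric noise — so sharper platforms score higher. Trimming makes
the statistic insensitive to a handful of extreme bins.

## Peak calling

Per chromosome, let x̄ and s be the mean and sample SD (ddof = 1) of the
masked-in enrichment values. Bins with value > x̄ + k·s seed candidate
regions; maximal runs of adjacent above-threshold bins are merged, and a
masked-out bin breaks a run (a region cannot span a probe gap). A candidate
of m bins with enrichment sum l is scored against L ~ N(m·x̄, m·s²) with the
upper-tail p-value 1 − Φ((l − m·x̄)/(s·√m)); q-values are Benjamini–Hochberg
across all candidates genome-wide and regions with q < FDR are significant
(defaults k = 0, FDR 0.05, minimum region one bin). Two caveats are
intentional properties of the heuristic rather than defects to fix: the
selection bias of scoring only above-threshold runs is left uncorrected (the
p-value is a ranking device, not a calibrated test), and "P(l > L)" is read
as the conventional upper tail of the null sum.

Peak sets are compared by the average proportion of overlapping peaks
(≥ 1 bp intersection, averaged over both directions) or by the overlap
fraction of the smaller set; top-N selection ranks by p, ties broken by
larger l and then genomic order so runs are reproducible even where p
underflows to 0.

## Meta-profiles

Genes shorter than 2 kb are excluded. TSS/TES anchors respect strand; the
80 bins of 50 bp spanning ±2 kb are extracted with minus-strand windows
reversed, so position 1 is always 2 kb upstream in the gene's own
orientation (required for TSS/TES asymmetry to be visible). Masked or
out-of-bounds bins are skipped per position rather than dropping whole
sites, preserving sample size across array coverage gaps. Averaged profiles
are z-scaled to mean 0 / variance 1. Overlapping genes are not deduplicated
(a flag-free design choice: each annotated gene contributes one window).

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions used by the tests and the
acceptance script:

- **Genome** — two chromosomes of 500 kb; GC track is Gaussian-smoothed white
  noise (correlation length 10 kb) standardized to mean 0.42 with typical
  excursions ±0.10 (fluctuation SD = amplitude/2), clipped to [0.05, 0.95].
  Fly-like GC level; the smooth track makes GC-bias detection a well-posed
  monotone problem.
- **Planted regions** — 50 non-overlapping regions, half narrow
  (500–1000 bp) and half broad (3–8 kb), multiplicative effects 4–8,
  snapped to the 50 bp grid with a ≥ 1 kb gap; the mix mirrors sharp
  (H3K4me3-like) versus broad (H3K27me3-like) mark geometry at effect sizes
  typical of clean histone-mark ChIP.
- **Reads** — fragment midpoints drawn per 50 bp bin with rate
  λ(x)·exp(β·(gc(x) − mean gc)); Poisson total around the requested depth;
  uniform strand; 5′ position at midpoint ∓ frag_len/2 (36 bp reads, 200 bp
  fragments). The exponential GC tilt guarantees positive rates and a
  monotone, tunable Spearman correlation with GC. Fragment length is fixed:
  no analysis here uses length variability.
- **Arrays** — probes tile every 50 bp; contiguous dropout blocks
  (exponential, mean 5 kb, rescaled so realized coverage hits the target
  exactly up to rounding) reduce coverage to 70 %, the coverage of the
  Agilent fly tiling design this emulates. Channels observe their rate
  track under independent multiplicative noise 2^ε, ε ~ N(0, 0.4²) in log2
  units. An optional smooth multiplicative `platform_bias` track, shared by
  all arrays simulated from it, stands in for probe-sequence and platform
  effects common to array replicates; it is what makes cross-platform
  correlation fall below both intra-platform correlations, as observed in
  real paired data.
- **Subsampling** — independent binomial thinning per read; the default
  ladder is 90 %, 80 %, …, 10 %, 5 %, 1 %.

All generators take explicit seeds (one experiment seed fans out to stage
seeds via `SeedSequence.spawn`) and are bit-for-bit reproducible.

Not emulated: sequence-level artefacts (mappability, duplicates, repeats),
copy-number variation, chromatin-structure effects on sonication, dye swap
or spatial array artefacts, fragment-length variability. Consequently a
passing recovery benchmark says the *analysis* behaves correctly under
GC-bias, depth and noise perturbations — not that these are the only biases
real libraries carry.

## Numerical choices

- Smoothing uses direct (non-FFT) convolution so results are exactly
  reproducible across platforms; masked bins contribute zero weight.
- Per-chromosome SDs use ddof = 1 ("sample standard deviation"); the
  skewness statistic uses 1/n moments as defined.
- p-values below ~1e-308 underflow to 0; the deterministic (p, l,
  coordinate) tie-break keeps rankings stable there.
- Hierarchical clustering of correlation matrices uses average linkage on
  1 − ρ, the conventional choice for correlation heat maps.
- Enrichment bins where the log-ratio is non-finite (possible only with a
  zero pseudocount) are masked out rather than propagated.
- Region placement uses rejection sampling, widest interval first, with a
  bounded retry budget; an over-packed request fails loudly.

## Problem sizes

Tests and the acceptance script run on 1 Mb genomes at depths of 10⁴–2×10⁶
reads, 20 seeded replicates for the recovery and input-swap directionality
checks and 10 for reproducibility ordering — sizes at which every binomial
or Poisson tolerance in the checks is several standard errors wide while a
full run stays in the seconds-to-minutes range on a laptop.

## Known limitations

- The peak caller's p-values are heuristically motivated and selection
  biased by design; they rank regions well but are not calibrated error
  probabilities.
- Peak calling at 1 kb resolution (the genome-wide default for the
  input-swap experiment) cannot resolve sub-kilobase features; recovery
  benchmarks use the 50 bp profiles for that reason. At 50 bp, an extremely
  shallow input (≲ 1 read/kb) makes the log-ratio numerator-dominated and
  inflates spurious single-bin peaks — visible in the package as the reversal
  of the deep-input advantage when calling at 50 bp against a 1 % input.
- GC bias is the only systematic input-DNA bias simulated; real input
  libraries also vary with chromatin preparation and sequencer run effects
  that have no generative model here.
- Meta-profiles average genes, not transcripts; isoform-level anchors are
  out of scope.
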