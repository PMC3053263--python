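# chipcompare

Cross-platform comparison of ChIP-chip and ChIP-seq profiles, with a focus on
what the **input-DNA background library** does to downstream analysis.

Chromatin immunoprecipitation read out by tiling microarray (ChIP-chip) or by
high-throughput sequencing (ChIP-seq) measures the same underlying
protein–DNA binding or histone-modification landscape through two very
different observation processes: two-channel probe intensities with partial
genomic coverage on the one side, GC-tilted read sampling whose stability
depends on sequencing depth on the other. `chipcompare` provides the
building blocks to compare the two measurements fairly — identical binning,
smoothing, normalization and peak-calling criteria applied to both — and to
quantify how the choice of input background (its depth, its GC bias)
reshapes enrichment profiles, TSS/TES signatures and peak calls. A paired
simulator observes one planted signal through both platform models, so every
claim can be tested against known ground truth.

Intended users: computational biologists doing epigenomic QC, and method
developers who need a controlled test bed for normalization and peak-calling
behaviour.

## What it computes

- **Enrichment profiles.** The genome is divided into 50 bp bins with centre
  coordinates $x_i$; read counts or probe intensities $y_i$ are smoothed with
  a normalized Gaussian kernel,
  $\tilde y_i = \sum_j w_{ij} y_j / \sum_j w_{ij}$ with
  $w_{ij} = \exp\!\big(-(x_j-x_i)^2 / 2h^2\big)$, bandwidth $h = 50$ bp,
  truncated to the 400 nearest bins. The per-bin enrichment is the log-ratio
  $\log_2(\mathrm{IP}_i/s_\mathrm{IP}) - \log_2(\mathrm{INPUT}_i/s_\mathrm{IN})$
  (library-size scaled for counts); input libraries themselves are profiled
  as $\log_2(\mathrm{INPUT}_i)$. Twenty adjacent bins are averaged for the
  1 kb genome-wide resolution.
- **Signal-to-noise.** Truncated skewness
  $m_3/m_2^{3/2}$ of the enrichment distribution after discarding the top
  and bottom 5 % of values — positively skewed profiles carry real
  enrichment above the noise.
- **Peak calling** (platform-agnostic heuristic): per chromosome, bins above
  $\bar x + k s$ are merged into candidate regions; a region of $m$ bins with
  enrichment sum $l$ gets the upper-tail p-value of
  $L \sim N(m\bar x,\, m s^2)$, i.e. $p = 1 - \Phi\big((l - m\bar x)/(s\sqrt m)\big)$,
  with Benjamini–Hochberg FDR control genome-wide (defaults $k=0$,
  FDR $<0.05$). Peak-set concordance is the average proportion of
  ≥ 1 bp-overlapping peaks.
- **Input QC.** Spearman correlation of input profiles with GC content,
  clustered correlation heat maps, binomial read subsampling at
  90 %…1 %, and coverage-versus-depth curves.
- **Meta-profiles.** Strand-aware averages of the 80 × 50 bp bins flanking
  TSS/TES of genes ≥ 2 kb, z-scaled to mean 0 / variance 1.
- **Synthetic data.** Toy genomes with smooth GC tracks, planted narrow and
  broad enrichment regions, reads drawn with rate
  $\lambda(x)\,e^{\beta(\mathrm{gc}(x)-\overline{\mathrm{gc}})}$, probe
  intensities with log-normal channel noise and ~70 % genomic coverage, plus
  the ground truth for recovery benchmarks.

## Worked example

```python
from chipcompare import synthetic as syn, profiles as pf, qc, peaks as pk

# one shared signal observed by both platforms
genome = syn.make_genome(n_chrom=2, lengths=[500_000, 500_000], seed=0)
truth, lam = syn.plant_regions(genome, n_regions=50, seed=1)
chip   = syn.simulate_reads(lam, genome, depth=2_000_000, seed=2)
input_ = syn.simulate_reads(lam.constant_like(1.0), genome, depth=2_000_000, seed=3)
probes = syn.simulate_array(lam, None, genome, coverage_target=0.7, noise_sd=0.4, seed=4)

seq       = pf.seq_profile(chip, input_, genome)      # 50 bp log2 enrichment
chip_chip = pf.array_profile(probes, genome)
seq_1kb   = pf.aggregate_bins(seq, 20)

peaks = pk.call_peaks(seq, k=0.0, fdr=0.05)
n, median_w, mean_w = pk.peak_stats(peaks)
recall, precision = pk.truth_recovery(truth, peaks, genome)
print(f"significant peaks: {n} (median width {median_w:.0f} bp)")
print(f"planted-region recall: {recall:.2f}, base-level precision: {precision:.3f}")
print(f"skewness (signal-to-noise) at 1 kb: {qc.truncated_skewness(seq_1kb):.2f}")
print(f"cross-platform Pearson r at 1 kb: "
      f"{qc.profile_correlation(seq_1kb, pf.aggregate_bins(chip_chip, 20)):.3f}")
```

prints

```
significant peaks: 50 (median width 3475 bp)
planted-region recall: 1.00, base-level precision: 0.965
skewness (signal-to-noise) at 1 kb: 2.01
cross-platform Pearson r at 1 kb: 0.983
```

All 50 planted regions are recovered at FDR 0.05 with 96.5 % of significant
peak bases inside planted regions; the 1 kb enrichment distribution is
strongly right-skewed (real signal), and the sequencing- and array-derived
profiles of the same underlying signal correlate at r ≈ 0.98 under these
noise settings.

## Command line

```bash
chipcompare simulate  --seed 1 --outdir data/          # genome, reads, probes, truth
chipcompare profile   --ip chip.bed --input input.bed --gc gc.bedgraph --out prof.bedgraph
chipcompare callpeaks --profile prof.bedgraph --k 0 --fdr 0.05 --out peaks.bed
chipcompare compare   --peaks a.bed b.bed --mode average
chipcompare qc-input  --inputs a.bed b.bed --gc gc.bedgraph --outdir qc/
chipcompare metaprofile --profile prof50.bedgraph --genes genes.bed --anchor tss --out meta.tsv
chipcompare run       --seed 1 --outdir experiment/    # full pipeline, demo config
```

Real data enters as plain text: mapped reads as BED6, tracks as bedGraph,
probes as TSV, genes as BED6 or GFF3.

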