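"""End-to-end orchestration of the synthetic comparison experiment.

``run_experiment`` drives simulate → profile → qc → peaks → metaprofiles on
one shared planted signal observed by both platforms, and writes every
result as deterministic plain-text tables.  Identical config + seed produce
byte-identical outputs; a manifest records the parameters and seeds used.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as cio
from . import metaprofiles as mp
from . import peaks as pk
from . import profiles as pf
from . import qc
from . import synthetic as syn
from .config import RunConfig

__all__ = ["run_experiment"]

FLOAT_FMT = "%.17g"


def _log(stage: str, msg: str) -> None:
    print(f"[chipcompare:{stage}] {msg}", file=sys.stderr)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def run_experiment(config: RunConfig, outdir: str, seed: Optional[int] = None) -> Path:
    """Run the full synthetic experiment and write results under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    seeds = syn.child_seeds(seed, 12)
    stage = "setup"
    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        g = config.genome
        genome = syn.make_genome(
            n_chrom=g.n_chrom, lengths=[g.chrom_length] * g.n_chrom, gc_mean=g.gc_mean,
            gc_amplitude=g.gc_amplitude, gc_scale=g.gc_scale, bin_size=g.bin_size,
            seed=seeds[0],
        )
        genes = syn.make_genes(genome, n_genes=config.genes.n_genes,
                               length_range=(config.genes.min_length, config.genes.max_length),
                               seed=seeds[1])
        genome = syn.add_promoter_gc_bump(genome, genes)
        r = config.regions
        truth, lam = syn.plant_regions(
            genome, n_regions=r.n_regions, narrow_width=r.narrow_width,
            broad_width=r.broad_width, narrow_fraction=r.narrow_fraction,
            effect_range=(r.effect_min, r.effect_max), min_gap=r.min_gap, seed=seeds[2],
        )
        rc = config.reads
        chip = syn.simulate_reads(lam, genome, depth=rc.chip_depth, gc_beta=rc.gc_beta,
                                  frag_len=rc.frag_len, read_len=rc.read_len, seed=seeds[3])
        input_matched = syn.simulate_reads(lam.constant_like(1.0), genome, depth=rc.input_depth,
                                           gc_beta=rc.gc_beta, frag_len=rc.frag_len,
                                           read_len=rc.read_len, seed=seeds[4])
        input_biased = syn.simulate_reads(lam.constant_like(1.0), genome, depth=rc.input_depth,
                                          gc_beta=rc.input_gc_beta, frag_len=rc.frag_len,
                                          read_len=rc.read_len, seed=seeds[5])
        a = config.array
        probes = syn.simulate_array(lam, None, genome, probe_spacing=a.probe_spacing,
                                    coverage_target=a.coverage_target, noise_sd=a.noise_sd,
                                    mean_dropout_block=a.mean_dropout_block, seed=seeds[6])
        cio.write_bedgraph(genome.gc_track, out / "gc.bedgraph", genome)
        cio.write_truth_bed(truth, out / "truth.bed")
        cio.write_genes_bed(genes, out / "genes.bed")
        cio.write_probes_tsv(probes, out / "probes.tsv")
        _log(stage, f"genome {genome.total_length} bp, {len(truth)} planted regions, "
                    f"{chip.total_reads} ChIP reads, {len(probes)} probes")

        # --- profiles -----------------------------------------------------
        stage = "profile"
        p = config.profile
        seq_prof = pf.seq_profile(chip, input_matched, genome, bin_size=p.bin_size,
                                  bandwidth=p.bandwidth, max_neighbors=p.max_neighbors,
                                  pseudocount=p.pseudocount, frag_len=rc.frag_len)
        arr_prof = pf.array_profile(probes, genome, bin_size=p.bin_size,
                                    bandwidth=p.bandwidth, max_neighbors=p.max_neighbors)
        seq_1kb = pf.aggregate_bins(seq_prof, p.aggregate)
        arr_1kb = pf.aggregate_bins(arr_prof, p.aggregate)
        cio.write_bedgraph(seq_prof.track, out / "profile_seq_50bp.bedgraph", genome)
        cio.write_bedgraph(arr_prof.track, out / "profile_chip_50bp.bedgraph", genome)
        cio.write_bedgraph(seq_1kb.track, out / "profile_seq_1kb.bedgraph", genome)
        _log(stage, "profiles built at 50 bp and aggregated")

        # --- qc -----------------------------------------------------------
        stage = "qc"
        in_prof_m = pf.seq_input_profile(input_matched, genome, bin_size=p.bin_size,
                                         bandwidth=p.bandwidth, aggregate=p.aggregate,
                                         frag_len=rc.frag_len)
        in_prof_b = pf.seq_input_profile(input_biased, genome, bin_size=p.bin_size,
                                         bandwidth=p.bandwidth, aggregate=p.aggregate,
                                         frag_len=rc.frag_len)
        skew_seq = qc.truncated_skewness(seq_1kb, trim=config.qc.trim)
        skew_arr = qc.truncated_skewness(arr_1kb, trim=config.qc.trim)
        r_cross = qc.profile_correlation(seq_1kb, arr_1kb, method="pearson")
        gc_m = qc.gc_correlation(in_prof_m, genome.gc_track)
        gc_b = qc.gc_correlation(in_prof_b, genome.gc_track)
        curve = qc.coverage_curve(input_biased, genome, ladder=config.qc.ladder, seed=seeds[7])
        corr = qc.correlation_heatmap(
            {"INPUT-matched": in_prof_m, "INPUT-biased": in_prof_b, "ChIP-seq": seq_1kb,
             "ChIP-chip": arr_1kb}, gc=genome.gc_track)
        _write_tsv(pd.DataFrame(
            [("skewness_seq_1kb", skew_seq), ("skewness_chip_1kb", skew_arr),
             ("pearson_seq_vs_chip_1kb", r_cross),
             ("spearman_gc_input_matched", gc_m), ("spearman_gc_input_biased", gc_b)],
            columns=["statistic", "value"]), out / "qc_summary.tsv")
        _write_tsv(curve.points, out / "coverage_curve.tsv")
        corr_df = corr.to_frame().reset_index().rename(columns={"index": "profile"})
        _write_tsv(corr_df, out / "correlation_matrix.tsv")
        (out / "correlation_leaf_order.txt").write_text("\n".join(corr.ordered_labels()) + "\n")
        _log(stage, f"skewness seq={skew_seq:.3f} chip={skew_arr:.3f}, cross-platform r={r_cross:.3f}")

        # --- peaks ----------------------------------------------------------
        stage = "peaks"
        kk, fdr = config.peaks.k, config.peaks.fdr
        seq_peaks = pk.call_peaks(seq_prof, k=kk, fdr=fdr)
        arr_peaks = pk.call_peaks(arr_prof, k=kk, fdr=fdr)
        cio.write_peaks(seq_peaks, out / "peaks_seq.bed")
        cio.write_peaks(arr_peaks, out / "peaks_chip.bed")
        n_s, med_s, mean_s = pk.peak_stats(seq_peaks)
        n_a, med_a, mean_a = pk.peak_stats(arr_peaks)
        try:
            top_overlap = pk.overlap_proportion(pk.top_n(seq_peaks, config.peaks.top_n),
                                                pk.top_n(arr_peaks, config.peaks.top_n),
                                                mode="average", significant_only=False)
        except ValueError:
            top_overlap = float("nan")
        swap_table, swap_overlap, _ = pk.input_swap_peaks(
            chip, {"matched": input_matched, "biased": input_biased,
                   "shallow": syn.subsample_reads(input_matched, 0.05, seed=seeds[8])},
            genome, k=kk, fdr=fdr, bin_size=p.bin_size, bandwidth=p.bandwidth,
            frag_len=rc.frag_len, pseudocount=p.pseudocount)
        _write_tsv(pd.DataFrame(
            [("seq", n_s, med_s, mean_s), ("chip", n_a, med_a, mean_a)],
            columns=["platform", "n_significant", "median_width", "mean_width"]),
            out / "peak_stats.tsv")
        _write_tsv(pd.DataFrame([("top_peak_overlap_average", top_overlap)],
                                columns=["statistic", "value"]), out / "peak_overlap.tsv")
        _write_tsv(swap_table, out / "input_swap_peaks.tsv")
        _write_tsv(swap_overlap.reset_index().rename(columns={"index": "input"}),
                   out / "input_swap_overlap.tsv")
        _log(stage, f"significant peaks: seq={n_s}, chip={n_a}")

        # --- metaprofiles -------------------------------------------------
        stage = "metaprofiles"
        kept = mp.select_genes(genes, config.genes.min_gene_length)
        if len(kept):
            metas, meta_corr = mp.input_swap_metaprofile(
                chip, {"matched": input_matched, "biased": input_biased}, genome, genes,
                anchor="tss", flank=config.genes.flank,
                min_gene_length=config.genes.min_gene_length,
                bin_size=p.bin_size, bandwidth=p.bandwidth, frag_len=rc.frag_len)
            meta_df = pd.DataFrame({"offset": metas["matched"].offsets})
            for name, m in metas.items():
                meta_df[name] = m.values
            _write_tsv(meta_df, out / "metaprofile_tss.tsv")
            _write_tsv(meta_corr, out / "metaprofile_correlations.tsv")
            _log(stage, f"meta-profiles over {metas['matched'].n_sites} TSSs")
        else:
            _log(stage, "no genes pass the length filter; meta-profiles skipped")

        if config.make_figures:
            stage = "figures"
            qc.plot_correlation_heatmap(corr, str(out / "correlation_heatmap.png"))
            qc.plot_coverage_curve(curve, str(out / "coverage_curve.png"))
            if len(kept):
                mp.plot_metaprofiles(metas, str(out / "metaprofile_tss.png"))
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "package": "chipcompare",
        "seed": seed,
        "stage_seeds": seeds,
        "config": config.model_dump(),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
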