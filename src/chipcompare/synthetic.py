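"""Paired-platform simulator: toy genomes, planted enrichment, reads and probes.

One shared per-bin enrichment rate track (λ) drives both observation models:

* sequencing reads — fragment midpoints are drawn with per-bin rate
  ``λ(x) · exp(β · (gc(x) − mean gc))``, so a positive ``gc_beta`` tilts the
  library toward GC-rich bins the way real input-DNA libraries are tilted;
  total read number is Poisson around the requested depth, a strand is
  assigned uniformly and the 5' position is offset from the midpoint by half a
  fragment length;
* two-channel tiling array — probes tile the genome with randomly dropped
  contiguous blocks (partial genomic coverage), and each channel observes its
  rate track under multiplicative log-normal noise.

All generators draw from ``numpy.random.default_rng`` seeded explicitly and
are reproducible bit for bit; a single experiment seed fans out to
per-stage child seeds via :func:`child_seeds`.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .core import BinnedTrack, GenomeModel, ReadSet, n_bins_for

__all__ = [
    "child_seeds",
    "make_genome",
    "plant_regions",
    "simulate_reads",
    "simulate_array",
    "subsample_reads",
    "make_genes",
    "add_promoter_gc_bump",
    "plant_tss_regions",
    "gc_rate_track",
    "SUBSAMPLE_LADDER",
]

#: Default read-subsampling ladder (proportions of the full library).
SUBSAMPLE_LADDER = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.01)


def child_seeds(seed: int, n: int) -> List[int]:
    """Fan a single experiment seed out into ``n`` independent stage seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def make_genome(
    n_chrom: int = 2,
    lengths: Optional[Sequence[int]] = None,
    gc_mean: float = 0.42,
    gc_amplitude: float = 0.10,
    gc_scale: int = 10_000,
    bin_size: int = 50,
    seed: int = 0,
) -> GenomeModel:
    """Generate a toy genome with a smoothly varying GC track.

    The GC track is Gaussian-smoothed white noise, standardized per chromosome
    and rescaled so typical excursions reach about ``gc_mean ± gc_amplitude``
    (fluctuation SD = ``gc_amplitude / 2``), then clipped to [0.05, 0.95].

    Parameters
    ----------
    gc_scale
        Correlation length of the GC fluctuations in bp.
    """
    if lengths is None:
        lengths = [500_000] * n_chrom
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have n_chrom entries")
    if not (0 < gc_mean < 1):
        raise ValueError(f"gc_mean must be in (0, 1), got {gc_mean}")
    if gc_amplitude < 0 or gc_mean - gc_amplitude <= 0 or gc_mean + gc_amplitude >= 1:
        raise ValueError("gc_mean ± gc_amplitude must stay within (0, 1)")
    if gc_scale <= 0:
        raise ValueError("gc_scale must be positive")

    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_lengths = {c: int(L) for c, L in zip(names, lengths)}
    gc_values: Dict[str, np.ndarray] = {}
    sigma_bins = gc_scale / bin_size
    for c in names:
        n = n_bins_for(chrom_lengths[c], bin_size)
        if gc_amplitude == 0:
            gc_values[c] = np.full(n, gc_mean)
            continue
        noise = rng.standard_normal(n)
        smooth = gaussian_filter1d(noise, sigma=sigma_bins, mode="reflect")
        sd = smooth.std()
        z = (smooth - smooth.mean()) / sd if sd > 0 else np.zeros(n)
        gc_values[c] = np.clip(gc_mean + (gc_amplitude / 2.0) * z, 0.05, 0.95)
    track = BinnedTrack(bin_size=bin_size, values=gc_values, value_kind="fraction")
    return GenomeModel(chrom_names=names, chrom_lengths=chrom_lengths, gc_track=track)


def _place_intervals(
    genome: GenomeModel,
    widths: Sequence[int],
    rng: np.random.Generator,
    min_gap: int,
    bin_size: int,
    max_tries_per_interval: int = 2000,
) -> List[Tuple[str, int, int]]:
    """Place non-overlapping intervals of the given widths, snapped to the bin grid.

    Wider intervals are placed first (rejection sampling packs much better
    that way); the returned list matches the input width order.
    """
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    chrom_p = np.array([genome.chrom_lengths[c] for c in genome.chrom_names], dtype=float)
    chrom_p /= chrom_p.sum()
    order = sorted(range(len(widths)), key=lambda i: -widths[i])
    out: List[Tuple[str, int, int]] = [("", 0, 0)] * len(widths)
    for pos_idx in order:
        width = widths[pos_idx]
        w = max(bin_size, int(round(width / bin_size)) * bin_size)
        for attempt in range(max_tries_per_interval):
            c = genome.chrom_names[rng.choice(len(chrom_p), p=chrom_p)]
            L = genome.chrom_lengths[c]
            if L <= w + 2 * min_gap:
                continue
            start = int(rng.integers(0, (L - w) // bin_size + 1)) * bin_size
            end = start + w
            if all(end + min_gap <= s or start >= e + min_gap for s, e in placed[c]):
                placed[c].append((start, end))
                out[pos_idx] = (c, start, end)
                break
        else:
            raise RuntimeError(
                f"could not place {len(widths)} non-overlapping intervals on this genome "
                f"(failed after {max_tries_per_interval} tries)"
            )
    return out


def plant_regions(
    genome: GenomeModel,
    n_regions: int = 50,
    narrow_width: Tuple[int, int] = (500, 1000),
    broad_width: Tuple[int, int] = (3000, 8000),
    narrow_fraction: float = 0.5,
    effect_range: Tuple[float, float] = (4.0, 8.0),
    min_gap: int = 1000,
    seed: int = 0,
) -> Tuple[pd.DataFrame, BinnedTrack]:
    """Plant non-overlapping enrichment regions and return (truth, λ track).

    Returns
    -------
    truth
        DataFrame with columns chrom, start, end, effect, width_class; region
        boundaries are snapped to the GC-track bin grid.
    lam
        Per-bin rate multiplier track: 1 outside regions, ``effect`` inside.
    """
    if effect_range[0] <= 1:
        raise ValueError("enrichment effects must exceed 1")
    if not (0 <= narrow_fraction <= 1):
        raise ValueError("narrow_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bin_size = genome.gc_track.bin_size
    lam = genome.empty_track(bin_size, value=1.0, value_kind="intensity")
    if n_regions == 0:
        truth = pd.DataFrame(columns=["chrom", "start", "end", "effect", "width_class"])
        return truth, lam

    classes = np.where(rng.random(n_regions) < narrow_fraction, "narrow", "broad")
    widths = [
        int(rng.integers(*(narrow_width if cls == "narrow" else broad_width), endpoint=True))
        for cls in classes
    ]
    intervals = _place_intervals(genome, widths, rng, min_gap=min_gap, bin_size=bin_size)
    effects = rng.uniform(effect_range[0], effect_range[1], size=n_regions)
    rows = []
    for (c, start, end), eff, cls in zip(intervals, effects, classes):
        lam.values[c][start // bin_size: end // bin_size] = eff
        rows.append((c, start, end, float(eff), cls))
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "effect", "width_class"])
    truth = truth.sort_values(["chrom", "start"]).reset_index(drop=True)
    return truth, lam


def gc_rate_track(genome: GenomeModel, gc_beta: float) -> BinnedTrack:
    """The multiplicative GC tilt ``exp(β·(gc − mean gc))`` as a track."""
    gbar = genome.mean_gc()
    vals = {c: np.exp(gc_beta * (genome.gc_track.values[c] - gbar)) for c in genome.chrom_names}
    return BinnedTrack(bin_size=genome.gc_track.bin_size, values=vals, value_kind="intensity")


def simulate_reads(
    lam: BinnedTrack,
    genome: GenomeModel,
    depth: int,
    gc_beta: float = 0.0,
    frag_len: int = 200,
    read_len: int = 36,
    seed: int = 0,
) -> ReadSet:
    """Draw sequencing reads whose local rate follows λ tilted by GC content.

    The per-bin fragment-midpoint rate is ``λ(x) · exp(β·(gc(x) − mean gc))``;
    the total read number is Poisson(depth).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if frag_len < read_len:
        raise ValueError("frag_len must be >= read_len")
    genome.gc_track.require_aligned(lam)
    rng = np.random.default_rng(seed)

    tilt = gc_rate_track(genome, gc_beta)
    bin_size = lam.bin_size
    rates = []
    for c in genome.chrom_names:
        r = lam.values[c] * tilt.values[c]
        # partial last bin contributes in proportion to its width
        widths = np.full(len(r), float(bin_size))
        widths[-1] = genome.chrom_lengths[c] - (len(r) - 1) * bin_size
        rates.append(r * widths / bin_size)
    flat = np.concatenate(rates)
    total_rate = flat.sum()
    if total_rate <= 0:
        raise ValueError("rate track is zero everywhere; cannot draw reads")
    probs = flat / total_rate

    n_reads = int(rng.poisson(depth))
    counts = rng.multinomial(n_reads, probs)

    positions: Dict[str, np.ndarray] = {}
    strands: Dict[str, np.ndarray] = {}
    offset = 0
    half = frag_len // 2
    for c, r in zip(genome.chrom_names, rates):
        nb = len(r)
        cnt = counts[offset: offset + nb]
        offset += nb
        total_c = int(cnt.sum())
        if total_c == 0:
            positions[c] = np.empty(0, dtype=np.int64)
            strands[c] = np.empty(0, dtype=bool)
            continue
        bin_idx = np.repeat(np.arange(nb), cnt)
        mid = bin_idx * bin_size + rng.random(total_c) * bin_size
        fwd = rng.random(total_c) < 0.5
        pos5 = np.where(fwd, mid - half, mid + half)
        pos5 = np.clip(np.floor(pos5).astype(np.int64), 0, genome.chrom_lengths[c] - 1)
        order = np.argsort(pos5, kind="stable")
        positions[c] = pos5[order]
        strands[c] = fwd[order]
    return ReadSet(read_length=read_len, positions=positions, strands=strands)


def _dropout_keep_mask(L: int, coverage: float, mean_block: float, rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Kept spans covering a ``coverage`` fraction of ``[0, L)``.

    Alternating kept/dropped runs with exponential lengths (dropped mean
    ``mean_block``); runs are rescaled so realized coverage hits the target
    up to integer rounding.
    """
    if coverage >= 1.0:
        return [(0, L)]
    mean_keep = mean_block * coverage / (1.0 - coverage)
    keeps, drops = [], []
    total = 0.0
    while total < L:
        k = rng.exponential(mean_keep)
        d = rng.exponential(mean_block)
        keeps.append(k)
        drops.append(d)
        total += k + d
    keeps = np.array(keeps) * (coverage * L / np.sum(keeps))
    drops = np.array(drops) * ((1.0 - coverage) * L / np.sum(drops))
    spans = []
    pos = 0.0
    for k, d in zip(keeps, drops):
        start, end = int(round(pos)), int(round(pos + k))
        if end > start:
            spans.append((start, min(end, L)))
        pos += k + d
    return spans


def simulate_array(
    lam: BinnedTrack,
    input_rate: Optional[BinnedTrack],
    genome: GenomeModel,
    probe_spacing: int = 50,
    coverage_target: float = 0.7,
    noise_sd: float = 0.4,
    platform_bias: Optional[BinnedTrack] = None,
    mean_dropout_block: float = 5000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a two-channel tiling array as a probe table.

    Probes of width ``probe_spacing`` tile the genome; contiguous blocks
    (exponential lengths, mean ``mean_dropout_block``) are dropped at random so
    probes cover ``coverage_target`` of the genome.  Channel intensities are
    ``ip = λ·bias·2^ε₁`` and ``input = input_rate·2^ε₂`` with independent
    ``ε ~ N(0, noise_sd²)`` per channel; ``platform_bias`` (if given) is a
    multiplicative track shared by every array simulated from it, standing in
    for probe/platform effects common to array replicates.

    Returns a DataFrame with columns
    chrom, start, end, probe_id, ip_intensity, input_intensity.
    """
    if not (0 < coverage_target <= 1):
        raise ValueError("coverage_target must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    genome.gc_track.require_aligned(lam)
    if input_rate is None:
        input_rate = lam.constant_like(1.0)
    lam.require_aligned(input_rate)
    rng = np.random.default_rng(seed)

    rows = []
    bin_size = lam.bin_size
    for c in genome.chrom_names:
        L = genome.chrom_lengths[c]
        starts = np.arange(0, L - probe_spacing + 1, probe_spacing, dtype=np.int64)
        spans = _dropout_keep_mask(L, coverage_target, mean_dropout_block, rng)
        mids = starts + probe_spacing // 2
        keep = np.zeros(len(starts), dtype=bool)
        span_starts = np.array([s for s, _ in spans])
        span_ends = np.array([e for _, e in spans])
        idx = np.searchsorted(span_starts, mids, side="right") - 1
        ok = idx >= 0
        keep[ok] = mids[ok] < span_ends[idx[ok]]
        starts = starts[keep]
        mids = mids[keep]
        bin_idx = np.minimum(mids // bin_size, len(lam.values[c]) - 1)
        ip_mean = lam.values[c][bin_idx]
        if platform_bias is not None:
            ip_mean = ip_mean * platform_bias.values[c][bin_idx]
        in_mean = input_rate.values[c][bin_idx]
        eps1 = rng.normal(0.0, noise_sd, size=len(starts))
        eps2 = rng.normal(0.0, noise_sd, size=len(starts))
        ip = ip_mean * np.exp2(eps1)
        inp = in_mean * np.exp2(eps2)
        for s, a, b in zip(starts, ip, inp):
            rows.append((c, int(s), int(s + probe_spacing), a, b))
    probes = pd.DataFrame(rows, columns=["chrom", "start", "end", "ip_intensity", "input_intensity"])
    probes.insert(3, "probe_id", [f"probe_{i}" for i in range(len(probes))])
    return probes


def subsample_reads(reads: ReadSet, proportion: float, seed: int = 0) -> ReadSet:
    """Binomial thinning: each read kept independently with the given probability."""
    if not (0 < proportion <= 1):
        raise ValueError(f"proportion must be in (0, 1], got {proportion}")
    if proportion == 1.0:
        return reads.copy()
    rng = np.random.default_rng(seed)
    positions, strands = {}, {}
    for c in reads.chroms:
        keep = rng.random(len(reads.positions[c])) < proportion
        positions[c] = reads.positions[c][keep]
        strands[c] = reads.strands[c][keep]
    return ReadSet(read_length=reads.read_length, positions=positions, strands=strands)


def make_genes(
    genome: GenomeModel,
    n_genes: int = 200,
    length_range: Tuple[int, int] = (800, 8000),
    min_gap: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Place non-overlapping gene models with uniform lengths and random strands."""
    rng = np.random.default_rng(seed)
    widths = rng.integers(length_range[0], length_range[1], size=n_genes, endpoint=True)
    intervals = _place_intervals(genome, list(widths), rng, min_gap=min_gap,
                                 bin_size=genome.gc_track.bin_size)
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
    genes = pd.DataFrame(
        [(c, s, e) for c, s, e in intervals], columns=["chrom", "start", "end"]
    )
    genes["strand"] = strand
    genes["gene_id"] = [f"gene_{i}" for i in range(n_genes)]
    return genes.sort_values(["chrom", "start"]).reset_index(drop=True)


def add_promoter_gc_bump(
    genome: GenomeModel,
    genes: pd.DataFrame,
    amplitude: float = 0.08,
    width: float = 300.0,
) -> GenomeModel:
    """Return a genome whose GC track carries a Gaussian bump at every TSS.

    Emulates the elevated GC content of promoters so TSS meta-profiles of
    GC-biased libraries acquire an anchored GC signature.
    """
    from .metaprofiles import anchor_sites  # local import to avoid a cycle

    gc = genome.gc_track.copy()
    bin_size = gc.bin_size
    for chrom, pos, _ in anchor_sites(genes, "tss"):
        centers = gc.bin_centers(chrom)
        gc.values[chrom] += amplitude * np.exp(-((centers - pos) ** 2) / (2 * width**2))
    for c in gc.chroms:
        gc.values[c] = np.clip(gc.values[c], 0.0, 1.0)
    return GenomeModel(chrom_names=genome.chrom_names,
                       chrom_lengths=dict(genome.chrom_lengths), gc_track=gc)


def plant_tss_regions(
    lam: BinnedTrack,
    genes: pd.DataFrame,
    effect: float,
    upstream: int = 500,
    downstream: int = 1500,
) -> BinnedTrack:
    """Multiply λ by ``effect`` in an oriented window around every TSS.

    ``effect < 1`` plants a repressive-mark-style depletion at promoters.
    """
    from .metaprofiles import anchor_sites

    if effect <= 0:
        raise ValueError("effect must be positive")
    out = lam.copy()
    b = out.bin_size
    for chrom, pos, strand in anchor_sites(genes, "tss"):
        if strand == "+":
            start, end = pos - upstream, pos + downstream
        else:
            start, end = pos - downstream, pos + upstream
        n = out.n_bins(chrom)
        i0 = max(0, int(start) // b)
        i1 = min(n, -(-int(end) // b))
        out.values[chrom][i0:i1] *= effect
    return out
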