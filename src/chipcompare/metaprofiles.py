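"""Average (meta) signal profiles around transcription start and end sites.

Genes of at least 2 kb are kept; the 80 bins of 50 bp spanning 2 kb up- and
downstream of each anchor are extracted in the gene's own orientation
(minus-strand windows are reversed), averaged position-wise across sites,
and z-scaled to mean 0 / variance 1 so profiles from different platforms or
normalizations are visually comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import BinnedTrack, EnrichmentProfile, MetaProfile

__all__ = [
    "select_genes",
    "anchor_sites",
    "average_profile",
    "scale_profile",
    "gc_metaprofile",
    "input_swap_metaprofile",
    "plot_metaprofiles",
]

GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id"]


def select_genes(genes: pd.DataFrame, min_length: int = 2000) -> pd.DataFrame:
    """Keep genes whose span is at least ``min_length`` bp (inclusive)."""
    lengths = genes["end"] - genes["start"]
    if (lengths <= 0).any():
        raise ValueError("gene records must satisfy start < end")
    return genes[lengths >= min_length].reset_index(drop=True)


def anchor_sites(genes: pd.DataFrame, anchor: str) -> List[Tuple[str, int, str]]:
    """(chrom, position, strand) anchors: TSS/TES respect gene orientation."""
    if anchor not in ("tss", "tes"):
        raise ValueError(f"anchor must be 'tss' or 'tes', got {anchor!r}")
    sites = []
    for row in genes.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {row.strand!r} for gene {row.gene_id!r}")
        at_start = (anchor == "tss") == (row.strand == "+")
        pos = row.start if at_start else row.end
        sites.append((row.chrom, int(pos), row.strand))
    return sites


def _as_profile(profile: Union[EnrichmentProfile, BinnedTrack]) -> EnrichmentProfile:
    if isinstance(profile, BinnedTrack):
        return EnrichmentProfile.from_track(profile, platform="other")
    return profile


def average_profile(
    profile: Union[EnrichmentProfile, BinnedTrack],
    sites: Sequence[Tuple[str, int, str]],
    anchor: str = "tss",
    flank: int = 2000,
) -> MetaProfile:
    """Position-wise mean of oriented windows around the anchor sites.

    Each site contributes its ``2·flank/bin`` flanking bin values, reversed
    for minus-strand sites; masked-out and out-of-bounds bins are skipped per
    position rather than dropping the whole site.
    """
    prof = _as_profile(profile)
    b = prof.bin_size
    if flank % b:
        raise ValueError(f"flank {flank} must be a multiple of the bin size {b}")
    half = flank // b
    width = 2 * half
    windows = np.full((len(sites), width), np.nan)
    for i, (chrom, pos, strand) in enumerate(sites):
        if chrom not in prof.track.values:
            continue
        vals = prof.track.values[chrom]
        mask = prof.mask[chrom]
        cb = int(pos) // b
        lo, hi = cb - half, cb + half
        src_lo, src_hi = max(lo, 0), min(hi, len(vals))
        if src_hi <= src_lo:
            continue
        win = np.full(width, np.nan)
        seg = np.where(mask[src_lo:src_hi], vals[src_lo:src_hi], np.nan)
        win[src_lo - lo: src_hi - lo] = seg
        if strand == "-":
            win = win[::-1]
        windows[i] = win
    contributing = np.isfinite(windows).any(axis=1).sum()
    if contributing == 0:
        raise ValueError("no usable anchor sites for the meta-profile")
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # positions with no in-bounds contributor are reported as NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(windows, axis=0)
    return MetaProfile(anchor=anchor, values=values, n_sites=int(contributing),
                       flank=flank, bin_size=b, scaled=False)


def scale_profile(p: MetaProfile) -> MetaProfile:
    """z-scale a meta-profile to mean 0 and variance 1 (1/n variance)."""
    v = p.values
    sd = v.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("meta-profile has zero variance; cannot scale")
    return replace(p, values=(v - v.mean()) / sd, scaled=True)


def gc_metaprofile(gc: BinnedTrack, sites, anchor: str = "tss", flank: int = 2000,
                   scaled: bool = True) -> MetaProfile:
    """Meta-profile of GC content itself around the anchors."""
    mp = average_profile(gc, sites, anchor=anchor, flank=flank)
    return scale_profile(mp) if scaled else mp


def input_swap_metaprofile(
    chip,
    inputs: Dict[str, object],
    genome,
    genes: pd.DataFrame,
    anchor: str = "tss",
    flank: int = 2000,
    min_gene_length: int = 2000,
    bin_size: int = 50,
    bandwidth: Optional[float] = 50.0,
    frag_len: int = 200,
) -> Tuple[Dict[str, MetaProfile], pd.DataFrame]:
    """Meta-profiles of one ChIP library normalized against several inputs.

    Returns the z-scaled meta-profile per input choice and a table of Pearson
    correlations between every pair of meta-profiles and against the GC
    meta-profile.  A mismatched (e.g. GC-biased) input imprints the GC
    signature around the anchors onto the ChIP profile, which this table
    quantifies.
    """
    from .profiles import seq_profile

    if len(inputs) < 2:
        raise ValueError("input-swap comparison needs at least 2 input libraries")
    kept = select_genes(genes, min_gene_length)
    sites = anchor_sites(kept, anchor)
    metas: Dict[str, MetaProfile] = {}
    for name, inp in inputs.items():
        prof = seq_profile(chip, inp, genome, bin_size=bin_size, bandwidth=bandwidth,
                           frag_len=frag_len, aggregate=1)
        metas[name] = scale_profile(average_profile(prof, sites, anchor=anchor, flank=flank))
    gc_meta = gc_metaprofile(genome.gc_track, sites, anchor=anchor, flank=flank)
    names = list(metas)
    rows = []
    for i, a in enumerate(names):
        for bname in names[i + 1:]:
            r = float(np.corrcoef(metas[a].values, metas[bname].values)[0, 1])
            rows.append((a, bname, r))
    for a in names:
        r = float(np.corrcoef(metas[a].values, gc_meta.values)[0, 1])
        rows.append((a, "GC", r))
    corr = pd.DataFrame(rows, columns=["profile_a", "profile_b", "pearson_r"])
    metas["GC"] = gc_meta
    return metas, corr


def plot_metaprofiles(metas: Dict[str, MetaProfile], path: str, anchor: str = "tss") -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 4))
    for name, mp in metas.items():
        ax.plot(mp.offsets, mp.values, label=name)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(f"distance from {anchor.upper()} (bp)")
    ax.set_ylabel("scaled signal")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
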