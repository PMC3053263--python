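"""Profile construction: binning, Gaussian smoothing, log-ratio enrichment.

The working resolution is 50 bp.  Reads (optionally shifted toward the
fragment midpoint) or probe intensities are binned, smoothed with a
normalized Gaussian kernel (bandwidth 50 bp, truncated to the 400 nearest
bins), and turned into per-bin log2 enrichment = IP over input after
library-size scaling.  Twenty adjacent 50 bp bins are averaged to obtain the
1 kb profiles used for genome-wide statistics.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.signal import convolve as _convolve

from .core import BinnedTrack, EnrichmentProfile, GenomeModel, ReadSet, n_bins_for

__all__ = [
    "shift_reads",
    "bin_counts",
    "bin_probes",
    "gaussian_smooth",
    "enrichment",
    "input_profile",
    "aggregate_bins",
    "variability_mask",
    "seq_profile",
    "array_profile",
    "seq_input_profile",
]

DEFAULT_BIN = 50
DEFAULT_BANDWIDTH = 50.0
DEFAULT_MAX_NEIGHBORS = 400
DEFAULT_AGGREGATE = 20
DEFAULT_PSEUDOCOUNT = 0.5


def shift_reads(reads: ReadSet, shift: int) -> ReadSet:
    """Shift 5' positions by a constant: +strand by ``+shift``, −strand by ``−shift``.

    With ``shift = frag_len // 2`` this moves each read to its fragment
    midpoint.  Positions are clipped to stay on the chromosome; clipping needs
    no genome because shifted positions are clipped against the maximum
    observed coordinate only when a genome is unavailable — callers that bin
    afterwards pass the genome there.
    """
    if shift == 0:
        return reads.copy()
    positions, strands = {}, {}
    for c in reads.chroms:
        pos = reads.positions[c].astype(np.int64)
        fwd = reads.strands[c]
        moved = np.where(fwd, pos + shift, pos - shift)
        positions[c] = np.maximum(moved, 0)
        strands[c] = fwd.copy()
    return ReadSet(read_length=reads.read_length, positions=positions, strands=strands)


def bin_counts(reads: ReadSet, genome: GenomeModel, bin_size: int = DEFAULT_BIN) -> BinnedTrack:
    """Count 5' read positions per bin (half-open bins; totals are conserved)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    values: Dict[str, np.ndarray] = {}
    for c in reads.chroms:
        if c not in genome.chrom_lengths:
            raise ValueError(f"reads on chromosome {c!r} absent from genome")
    for c in genome.chrom_names:
        n = genome.n_bins(c, bin_size)
        pos = reads.positions.get(c)
        if pos is None or len(pos) == 0:
            values[c] = np.zeros(n)
            continue
        clipped = np.minimum(pos, genome.chrom_lengths[c] - 1)
        values[c] = np.bincount(clipped // bin_size, minlength=n).astype(float)
    return BinnedTrack(bin_size=bin_size, values=values, value_kind="count")


def bin_probes(
    probes, genome: GenomeModel, bin_size: int = DEFAULT_BIN
) -> Tuple[BinnedTrack, BinnedTrack, Dict[str, np.ndarray]]:
    """Average probe intensities per bin by probe midpoint.

    Returns (ip track, input track, probe mask); bins containing no probe
    midpoint get value 0 and mask False.
    """
    ip_vals: Dict[str, np.ndarray] = {}
    in_vals: Dict[str, np.ndarray] = {}
    mask: Dict[str, np.ndarray] = {}
    for c in genome.chrom_names:
        n = genome.n_bins(c, bin_size)
        sub = probes[probes["chrom"] == c]
        ip = np.zeros(n)
        inp = np.zeros(n)
        cnt = np.zeros(n)
        if len(sub):
            mids = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
            idx = np.minimum(mids // bin_size, n - 1)
            np.add.at(ip, idx, sub["ip_intensity"].to_numpy(float))
            np.add.at(inp, idx, sub["input_intensity"].to_numpy(float))
            np.add.at(cnt, idx, 1.0)
        has = cnt > 0
        ip[has] /= cnt[has]
        inp[has] /= cnt[has]
        ip_vals[c], in_vals[c], mask[c] = ip, inp, has
    return (
        BinnedTrack(bin_size=bin_size, values=ip_vals, value_kind="intensity"),
        BinnedTrack(bin_size=bin_size, values=in_vals, value_kind="intensity"),
        mask,
    )


def _kernel(bin_size: int, bandwidth: float, max_neighbors: int, printed_kernel: bool) -> np.ndarray:
    half = max_neighbors // 2
    offsets = np.arange(-half, half + 1, dtype=float) * bin_size
    if printed_kernel:
        # literal transcription of the published formula; grows with distance
        # and is kept only for comparison
        return np.exp(offsets**2 / bandwidth)
    return np.exp(-(offsets**2) / (2.0 * bandwidth**2))


def gaussian_smooth(
    track: BinnedTrack,
    bandwidth: float = DEFAULT_BANDWIDTH,
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
    mask: Optional[Dict[str, np.ndarray]] = None,
    normalize: bool = True,
    printed_kernel: bool = False,
) -> BinnedTrack:
    """Nadaraya–Watson Gaussian smoothing truncated to the nearest bins.

    ``y_i ← Σ_j w_ij y_j / Σ_j w_ij`` with ``w_ij = exp(−(x_j−x_i)²/(2·h²))``,
    the sum over the ``max_neighbors`` nearest bins on the same chromosome
    (one-sided at chromosome ends).  Masked-out bins, if a mask is given,
    contribute no weight.  Normalization preserves constants and makes the
    operator linear in the values.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if max_neighbors <= 0 or max_neighbors % 2:
        raise ValueError("max_neighbors must be a positive even count")
    if not track.values:
        raise ValueError("cannot smooth an empty track")
    w = _kernel(track.bin_size, bandwidth, max_neighbors, printed_kernel)
    out: Dict[str, np.ndarray] = {}
    for c, v in track.values.items():
        if len(v) == 0:
            raise ValueError(f"cannot smooth empty chromosome {c!r}")
        m = np.ones(len(v)) if mask is None else mask[c].astype(float)
        # scipy's convolve keeps "same" relative to the signal even when the
        # truncated kernel is longer than a short chromosome
        num = _convolve(v * m, w, mode="same", method="direct")
        if normalize:
            den = _convolve(m, w, mode="same", method="direct")
            with np.errstate(invalid="ignore", divide="ignore"):
                sm = np.where(den > 0, num / den, 0.0)
        else:
            sm = num
        out[c] = sm
    return BinnedTrack(bin_size=track.bin_size, values=out, value_kind=track.value_kind)


def _combine_masks(track: BinnedTrack, mask: Optional[Dict[str, np.ndarray]]) -> Dict[str, np.ndarray]:
    if mask is None:
        return {c: np.ones(track.n_bins(c), dtype=bool) for c in track.chroms}
    return {c: np.asarray(mask[c], dtype=bool) for c in track.chroms}


def enrichment(
    ip: BinnedTrack,
    input_: BinnedTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    mask: Optional[Dict[str, np.ndarray]] = None,
    platform: str = "seq",
) -> EnrichmentProfile:
    """Per-bin log2 enrichment of IP over input.

    ``value_i = log2((ip_i + c)/s_ip) − log2((input_i + c)/s_in)`` where the
    scaling totals ``s`` are the genome-wide sums for count tracks (library
    size normalization) and 1 for intensity tracks; ``c`` is the pseudocount
    for count tracks and 0 for intensity tracks (intensities are strictly
    positive already).
    """
    ip.require_aligned(input_)
    m = _combine_masks(ip, mask)

    def scale_and_pc(track: BinnedTrack) -> Tuple[float, float]:
        if track.value_kind == "count":
            if pseudocount <= 0:
                raise ValueError("pseudocount must be > 0 for count tracks")
            return max(track.total(), 1.0), pseudocount
        return 1.0, 0.0

    s_ip, c_ip = scale_and_pc(ip)
    s_in, c_in = scale_and_pc(input_)
    values: Dict[str, np.ndarray] = {}
    for c in ip.chroms:
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.log2((ip.values[c] + c_ip) / s_ip) - np.log2((input_.values[c] + c_in) / s_in)
        bad = ~np.isfinite(v)
        m[c] = m[c] & ~bad
        v[bad] = 0.0
        values[c] = v
    track = BinnedTrack(bin_size=ip.bin_size, values=values, value_kind="log-ratio")
    return EnrichmentProfile(track=track, platform=platform, mask=m, pseudocount=pseudocount)


def input_profile(
    input_: BinnedTrack,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    mask: Optional[Dict[str, np.ndarray]] = None,
) -> EnrichmentProfile:
    """log2 of the input signal itself, as the enrichment measure of input libraries."""
    m = _combine_masks(input_, mask)
    pc = pseudocount if input_.value_kind == "count" else 0.0
    values: Dict[str, np.ndarray] = {}
    for c in input_.chroms:
        if np.any(input_.values[c] < 0):
            raise ValueError(f"negative input values on {c!r}")
        with np.errstate(divide="ignore"):
            v = np.log2(input_.values[c] + pc)
        bad = ~np.isfinite(v)
        m[c] = m[c] & ~bad
        v[bad] = 0.0
        values[c] = v
    track = BinnedTrack(bin_size=input_.bin_size, values=values, value_kind="log-ratio")
    return EnrichmentProfile(track=track, platform="input", mask=m, pseudocount=pc)


def aggregate_bins(profile: EnrichmentProfile, factor: int = DEFAULT_AGGREGATE) -> EnrichmentProfile:
    """Average every ``factor`` adjacent bins, skipping masked-out children.

    An output bin is masked out only when all of its children are; the bin
    size multiplies by ``factor``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return profile.copy()
    values: Dict[str, np.ndarray] = {}
    masks: Dict[str, np.ndarray] = {}
    b = profile.bin_size
    for c in profile.chroms:
        v = profile.track.values[c]
        m = profile.mask[c]
        n_out = n_bins_for(len(v), factor)
        pad = n_out * factor - len(v)
        vp = np.concatenate([np.where(m, v, 0.0), np.zeros(pad)]).reshape(n_out, factor)
        mp = np.concatenate([m.astype(float), np.zeros(pad)]).reshape(n_out, factor)
        cnt = mp.sum(axis=1)
        with np.errstate(invalid="ignore"):
            out = np.where(cnt > 0, vp.sum(axis=1) / np.maximum(cnt, 1), 0.0)
        values[c] = out
        masks[c] = cnt > 0
    track = BinnedTrack(bin_size=b * factor, values=values, value_kind="log-ratio")
    return EnrichmentProfile(track=track, platform=profile.platform, mask=masks,
                             bandwidth=profile.bandwidth, pseudocount=profile.pseudocount)


def variability_mask(inputs: List[EnrichmentProfile], quantile: float = 0.95) -> Dict[str, np.ndarray]:
    """Mask out bins whose across-input SD exceeds the genome-wide SD quantile.

    Emulates the exclusion of regions with unusually high input-library
    variability before computing reproducibility statistics.  Returns a
    per-bin boolean mask (True = keep) to be AND-combined with probe masks.
    """
    if len(inputs) < 2:
        raise ValueError("variability masking needs at least 2 input profiles")
    first = inputs[0]
    for other in inputs[1:]:
        first.track.require_aligned(other.track)
    sds: Dict[str, np.ndarray] = {}
    all_sd = []
    for c in first.chroms:
        stack = np.stack([p.track.values[c] for p in inputs])
        joint = np.logical_and.reduce([p.mask[c] for p in inputs])
        sd = stack.std(axis=0, ddof=0)
        sd[~joint] = np.nan
        sds[c] = sd
        all_sd.append(sd[joint])
    pooled = np.concatenate(all_sd)
    if len(pooled) == 0:
        raise ValueError("no jointly masked-in bins across the input profiles")
    cut = float(np.quantile(pooled, quantile))
    out: Dict[str, np.ndarray] = {}
    for c in first.chroms:
        sd = sds[c]
        keep = np.ones(len(sd), dtype=bool)
        with np.errstate(invalid="ignore"):
            keep[np.nan_to_num(sd, nan=-np.inf) > cut] = False
        out[c] = keep
    return out


# ---------------------------------------------------------------------------
# Pipeline helpers: raw observations -> enrichment profiles
# ---------------------------------------------------------------------------

def seq_profile(
    chip: ReadSet,
    input_: ReadSet,
    genome: GenomeModel,
    bin_size: int = DEFAULT_BIN,
    shift: Optional[int] = None,
    frag_len: int = 200,
    bandwidth: Optional[float] = DEFAULT_BANDWIDTH,
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    aggregate: int = 1,
) -> EnrichmentProfile:
    """Full ChIP-seq pipeline: shift, bin, smooth both libraries, log-ratio, aggregate."""
    if shift is None:
        shift = frag_len // 2
    ip_track = bin_counts(shift_reads(chip, shift), genome, bin_size)
    in_track = bin_counts(shift_reads(input_, shift), genome, bin_size)
    if bandwidth is not None:
        ip_track = gaussian_smooth(ip_track, bandwidth, max_neighbors)
        in_track = gaussian_smooth(in_track, bandwidth, max_neighbors)
    prof = enrichment(ip_track, in_track, pseudocount=pseudocount, platform="seq")
    prof.bandwidth = bandwidth
    return aggregate_bins(prof, aggregate) if aggregate > 1 else prof


def array_profile(
    probes,
    genome: GenomeModel,
    bin_size: int = DEFAULT_BIN,
    bandwidth: Optional[float] = DEFAULT_BANDWIDTH,
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
    aggregate: int = 1,
) -> EnrichmentProfile:
    """Full ChIP-chip pipeline: bin probes, smooth within coverage, log-ratio, aggregate."""
    ip_track, in_track, probe_mask = bin_probes(probes, genome, bin_size)
    if bandwidth is not None:
        ip_track = gaussian_smooth(ip_track, bandwidth, max_neighbors, mask=probe_mask)
        in_track = gaussian_smooth(in_track, bandwidth, max_neighbors, mask=probe_mask)
    prof = enrichment(ip_track, in_track, mask=probe_mask, platform="chip")
    prof.bandwidth = bandwidth
    return aggregate_bins(prof, aggregate) if aggregate > 1 else prof


def seq_input_profile(
    input_: ReadSet,
    genome: GenomeModel,
    bin_size: int = DEFAULT_BIN,
    shift: Optional[int] = None,
    frag_len: int = 200,
    bandwidth: Optional[float] = DEFAULT_BANDWIDTH,
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    aggregate: int = 1,
) -> EnrichmentProfile:
    """Input-library profile: log2 of the (smoothed) binned input read counts."""
    if shift is None:
        shift = frag_len // 2
    track = bin_counts(shift_reads(input_, shift), genome, bin_size)
    if bandwidth is not None:
        track = gaussian_smooth(track, bandwidth, max_neighbors)
    prof = input_profile(track, pseudocount=pseudocount)
    prof.bandwidth = bandwidth
    return aggregate_bins(prof, aggregate) if aggregate > 1 else prof
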