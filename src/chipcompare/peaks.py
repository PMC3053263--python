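"""Platform-agnostic heuristic peak caller with Benjamini–Hochberg FDR.

The caller works on any binned enrichment profile, array- or
sequencing-derived, which is what makes cross-platform peak comparisons
fair.  Per chromosome, bins with enrichment above ``x̄ + k·s`` (mean and
sample SD of the masked-in bins) are selected and runs of adjacent
above-threshold bins are merged into candidate regions; a masked-out bin
breaks a run.  A candidate of ``m`` bins with enrichment sum ``l`` is scored
against the null ``L ~ N(m·x̄, m·s²)`` with the upper-tail p-value
``1 − Φ((l − m·x̄)/(s·√m))``; q-values come from Benjamini–Hochberg across
all candidates genome-wide, and candidates with q below the FDR threshold
are flagged significant.  The selection bias of testing only
above-threshold runs is deliberately left uncorrected: the statistic is a
ranking heuristic, not a calibrated test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core import EnrichmentProfile, GenomeModel, ReadSet

__all__ = [
    "PeakSet",
    "call_peaks",
    "bh_adjust",
    "peak_stats",
    "top_n",
    "overlap_proportion",
    "truth_recovery",
    "input_swap_peaks",
]

REGION_COLUMNS = ["chrom", "start", "end", "m", "l", "p", "q", "significant"]


@dataclass
class PeakSet:
    """Candidate enrichment regions with their scores and significance calls."""

    regions: pd.DataFrame  # columns REGION_COLUMNS, sorted by (chrom, start)
    bin_size: int
    k: float
    fdr: float
    source: Optional[str] = None

    def __post_init__(self) -> None:
        missing = [c for c in REGION_COLUMNS if c not in self.regions.columns]
        if missing:
            raise ValueError(f"peak table missing columns {missing}")

    def __len__(self) -> int:
        return len(self.regions)

    def significant(self) -> pd.DataFrame:
        return self.regions[self.regions["significant"]].reset_index(drop=True)

    def subset(self, idx) -> "PeakSet":
        return PeakSet(
            regions=self.regions.loc[idx].sort_values(["chrom", "start"]).reset_index(drop=True),
            bin_size=self.bin_size, k=self.k, fdr=self.fdr, source=self.source,
        )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _runs(above: np.ndarray) -> List[Tuple[int, int]]:
    """(start, stop) index pairs of maximal True runs."""
    padded = np.concatenate([[False], above, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def call_peaks(profile: EnrichmentProfile, k: float = 0.0, fdr: float = 0.05) -> PeakSet:
    """Two-step heuristic peak calling on a binned enrichment profile.

    Parameters
    ----------
    k
        Threshold stringency: bins above ``x̄ + k·s`` seed candidate regions
        (``k = 0`` thresholds at the per-chromosome mean).
    fdr
        Benjamini–Hochberg threshold; candidates with ``q < fdr`` are flagged
        significant.
    """
    rows = []
    bin_size = profile.bin_size
    for c in profile.chroms:
        vals = profile.track.values[c]
        mask = profile.mask[c]
        used = vals[mask]
        if len(used) == 0:
            raise ValueError(f"no masked-in bins on chromosome {c!r}")
        xbar = float(used.mean())
        s = float(used.std(ddof=1)) if len(used) > 1 else 0.0
        if s == 0.0:
            raise ValueError(f"zero enrichment variance on chromosome {c!r}; peaks undefined")
        above = (vals > xbar + k * s) & mask
        for i0, i1 in _runs(above):
            m = i1 - i0
            l = float(vals[i0:i1].sum())
            z = (l - m * xbar) / (s * np.sqrt(m))
            p = float(norm.sf(z))
            rows.append((c, int(i0 * bin_size), int(i1 * bin_size), int(m), l, p))
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "m", "l", "p"])
    if len(regions):
        regions["q"] = bh_adjust(regions["p"].to_numpy())
        regions["significant"] = regions["q"] < fdr
    else:
        regions["q"] = pd.Series(dtype=float)
        regions["significant"] = pd.Series(dtype=bool)
    regions = regions.sort_values(["chrom", "start"]).reset_index(drop=True)
    return PeakSet(regions=regions, bin_size=bin_size, k=k, fdr=fdr)


def peak_stats(peaks: PeakSet, significant_only: bool = True) -> Tuple[int, float, float]:
    """(count, median width, mean width) of the (significant) regions."""
    df = peaks.significant() if significant_only else peaks.regions
    if len(df) == 0:
        return 0, 0.0, 0.0
    widths = (df["end"] - df["start"]).to_numpy()
    return len(df), float(np.median(widths)), float(widths.mean())


def top_n(peaks: PeakSet, n: int = 1000) -> PeakSet:
    """The ``n`` best regions by smallest p, ties broken by larger l then coordinates."""
    if n < 1:
        raise ValueError("n must be >= 1")
    df = peaks.regions
    order = df.sort_values(["p", "l", "chrom", "start"],
                           ascending=[True, False, True, True], kind="mergesort")
    return peaks.subset(order.index[:n])


def _any_overlap(df_a: pd.DataFrame, df_b: pd.DataFrame) -> np.ndarray:
    """For each region of A, whether it intersects any region of B by >= 1 bp."""
    hit = np.zeros(len(df_a), dtype=bool)
    for c, sub_a in df_a.groupby("chrom", sort=False):
        sub_b = df_b[df_b["chrom"] == c]
        if len(sub_b) == 0:
            continue
        b_starts = sub_b["start"].to_numpy()
        b_ends = sub_b["end"].to_numpy()
        order = np.argsort(b_starts)
        b_starts, b_ends = b_starts[order], b_ends[order]
        # B regions are non-overlapping: a query [s,e) hits iff the last region
        # starting before e extends past s
        idx = np.searchsorted(b_starts, sub_a["end"].to_numpy(), side="left") - 1
        ok = idx >= 0
        res = np.zeros(len(sub_a), dtype=bool)
        res[ok] = b_ends[idx[ok]] > sub_a["start"].to_numpy()[ok]
        hit[df_a.index.get_indexer(sub_a.index)] = res
    return hit


def overlap_proportion(a: PeakSet, b: PeakSet, mode: str = "average",
                       significant_only: bool = True) -> float:
    """Concordance of two peak sets by 1-bp interval intersection.

    ``mode="average"``: mean of the two directional overlap fractions.
    ``mode="smaller"``: overlap fraction of the smaller set.
    """
    df_a = (a.significant() if significant_only else a.regions).reset_index(drop=True)
    df_b = (b.significant() if significant_only else b.regions).reset_index(drop=True)
    if len(df_a) == 0 or len(df_b) == 0:
        raise ValueError("overlap proportion is undefined for an empty peak set")
    frac_a = _any_overlap(df_a, df_b).mean()
    frac_b = _any_overlap(df_b, df_a).mean()
    if mode == "average":
        return float((frac_a + frac_b) / 2.0)
    if mode == "smaller":
        return float(frac_a if len(df_a) <= len(df_b) else frac_b)
    raise ValueError(f"unknown overlap mode {mode!r}")


def truth_recovery(truth: pd.DataFrame, peaks: PeakSet,
                   genome: GenomeModel) -> Tuple[float, float]:
    """(recall, base-level precision) of significant peaks against planted truth.

    Recall: fraction of planted regions intersecting a significant peak by
    ≥ 1 bp.  Precision: fraction of significant-peak bases lying inside a
    planted region.
    """
    sig = peaks.significant()
    if len(truth) == 0:
        raise ValueError("truth set is empty; recovery undefined")
    recall = float(_any_overlap(truth.reset_index(drop=True), sig).mean())
    tp = fp = 0
    for c, sub in sig.groupby("chrom"):
        covered = np.zeros(genome.chrom_lengths[c], dtype=bool)
        for r in truth[truth["chrom"] == c].itertuples():
            covered[r.start:r.end] = True
        for r in sub.itertuples():
            seg = covered[r.start:r.end]
            tp += int(seg.sum())
            fp += int(len(seg) - seg.sum())
    precision = tp / max(tp + fp, 1)
    return recall, float(precision)


def input_swap_peaks(
    chip: ReadSet,
    inputs: Dict[str, ReadSet],
    genome: GenomeModel,
    k: float = 0.0,
    fdr: float = 0.05,
    bin_size: int = 50,
    bandwidth: Optional[float] = 50.0,
    aggregate: int = 20,
    frag_len: int = 200,
    pseudocount: float = 0.5,
) -> Tuple[pd.DataFrame, pd.DataFrame, Dict[str, PeakSet]]:
    """Call peaks for one ChIP library against several candidate input libraries.

    Returns (per-input summary table, pairwise overlap matrix of the
    significant peak sets, the peak sets themselves).  The summary quantifies
    how strongly the choice of input background sways peak number and width.
    Peaks are called at the 1 kb genome-wide analysis resolution by default
    (``aggregate=20`` over 50 bp bins).
    """
    from .profiles import seq_profile

    if len(inputs) < 2:
        raise ValueError("input-swap comparison needs at least 2 input libraries")
    peak_sets: Dict[str, PeakSet] = {}
    rows = []
    for name, inp in inputs.items():
        prof = seq_profile(chip, inp, genome, bin_size=bin_size, bandwidth=bandwidth,
                           aggregate=aggregate, frag_len=frag_len, pseudocount=pseudocount)
        ps = call_peaks(prof, k=k, fdr=fdr)
        ps.source = name
        peak_sets[name] = ps
        count, med_w, mean_w = peak_stats(ps)
        rows.append((name, inp.total_reads, count, med_w, mean_w))
    table = pd.DataFrame(rows, columns=["input", "input_depth", "n_peaks",
                                        "median_width", "mean_width"])
    names = list(inputs)
    overlap = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, ni in enumerate(names):
        for j in range(i + 1, len(names)):
            nj = names[j]
            try:
                o = overlap_proportion(peak_sets[ni], peak_sets[nj], mode="average")
            except ValueError:
                o = np.nan
            overlap.iloc[i, j] = overlap.iloc[j, i] = o
    return table, overlap, peak_sets
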