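"""Signal-to-noise, reproducibility, GC-bias and coverage statistics.

Implements the profile-level quality measures: truncated skewness as a
signal-to-noise proxy, masked Pearson/Spearman correlations between
profiles, Spearman correlation of input profiles with GC content, a
clustered correlation heat map, and sequencing-depth/coverage curves built
by binomial read subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average as average_linkage
from scipy.cluster.hierarchy import leaves_list
from scipy.spatial.distance import squareform

from .core import BinnedTrack, EnrichmentProfile, GenomeModel, ReadSet
from .synthetic import SUBSAMPLE_LADDER, child_seeds, subsample_reads

__all__ = [
    "truncated_skewness",
    "profile_correlation",
    "gc_correlation",
    "CorrelationMatrix",
    "correlation_heatmap",
    "genomic_coverage",
    "coverage_curve",
    "plot_correlation_heatmap",
    "plot_coverage_curve",
]


def truncated_skewness(
    profile: Union[EnrichmentProfile, np.ndarray], trim: float = 0.05
) -> float:
    """Skewness m₃/m₂^{3/2} (1/n moments) after trimming both tails by rank.

    The lowest and highest ``trim`` fractions of the masked-in enrichment
    values (``floor(n·trim)`` values per tail) are removed before the third
    standardized moment is computed.  Positive values indicate a long right
    tail, i.e. genuine enrichment standing out of the noise.
    """
    if not (0 <= trim < 0.5):
        raise ValueError("trim must be in [0, 0.5)")
    x = profile.masked_values() if isinstance(profile, EnrichmentProfile) else np.asarray(profile, float)
    x = np.sort(x)
    k = int(np.floor(len(x) * trim))
    if k > 0:
        x = x[k:-k]
    if len(x) < 10:
        raise ValueError(f"too few values after trimming ({len(x)}); need at least 10")
    m2 = np.mean((x - x.mean()) ** 2)
    if m2 == 0:
        raise ValueError("zero variance after trimming; skewness undefined")
    return float(stats.skew(x, bias=True))


def _joint_values(a: EnrichmentProfile, b: EnrichmentProfile) -> Tuple[np.ndarray, np.ndarray]:
    a.track.require_aligned(b.track)
    xs, ys = [], []
    for c in a.chroms:
        joint = a.mask[c] & b.mask[c]
        xs.append(a.track.values[c][joint])
        ys.append(b.track.values[c][joint])
    return np.concatenate(xs), np.concatenate(ys)


def profile_correlation(a: EnrichmentProfile, b: EnrichmentProfile, method: str = "pearson") -> float:
    """Correlation between two profiles on bins masked-in for both."""
    x, y = _joint_values(a, b)
    if len(x) < 3:
        raise ValueError(f"only {len(x)} jointly masked-in bins; need at least 3")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def gc_correlation(input_profile: EnrichmentProfile, gc: BinnedTrack) -> float:
    """Spearman correlation of an input profile with GC content.

    The GC track is mean-aggregated to the profile's bin size if needed.
    """
    if gc.bin_size != input_profile.bin_size:
        factor, rem = divmod(input_profile.bin_size, gc.bin_size)
        if rem or factor < 1:
            raise ValueError(
                f"GC bin size {gc.bin_size} does not divide profile bin size {input_profile.bin_size}"
            )
        gc = gc.aggregate(factor)
    gc_profile = EnrichmentProfile.from_track(gc, platform="gc")
    return profile_correlation(input_profile, gc_profile, method="spearman")


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise correlation matrix with a clustering leaf order."""

    labels: List[str]
    values: np.ndarray
    method: str
    leaf_order: List[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def ordered_labels(self) -> List[str]:
        return [self.labels[i] for i in self.leaf_order]


def correlation_heatmap(
    profiles: Dict[str, EnrichmentProfile],
    gc: Optional[BinnedTrack] = None,
    method: str = "spearman",
) -> CorrelationMatrix:
    """Pairwise correlations between profiles (and optionally GC), clustered.

    Each pair is correlated on its own joint mask.  Hierarchical clustering
    uses average linkage on the distance ``1 − ρ``; the returned leaf order is
    the dendrogram's left-to-right leaf sequence.
    """
    items = dict(profiles)
    if gc is not None:
        ref_bin = next(iter(items.values())).bin_size
        gc_t = gc if gc.bin_size == ref_bin else gc.aggregate(ref_bin // gc.bin_size)
        items["GC"] = EnrichmentProfile.from_track(gc_t, platform="gc")
    labels = list(items)
    if len(labels) < 2:
        raise ValueError("need at least 2 profiles")
    n = len(labels)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            r = profile_correlation(items[labels[i]], items[labels[j]], method=method)
            mat[i, j] = mat[j, i] = r
    dist = np.clip(1.0 - mat, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(average_linkage(squareform(dist, checks=False)))
    return CorrelationMatrix(labels=labels, values=mat, method=method, leaf_order=[int(i) for i in order])


def genomic_coverage(reads: ReadSet, genome: GenomeModel) -> float:
    """Fraction of genome bases covered by at least one read interval."""
    covered = 0
    for c in genome.chrom_names:
        L = genome.chrom_lengths[c]
        pos = reads.positions.get(c)
        if pos is None or len(pos) == 0:
            continue
        starts = np.minimum(pos, L - 1)
        ends = np.minimum(starts + reads.read_length, L)
        delta = np.zeros(L + 1, dtype=np.int32)
        np.add.at(delta, starts, 1)
        np.add.at(delta, ends, -1)
        covered += int(np.count_nonzero(np.cumsum(delta[:-1]) > 0))
    return covered / genome.total_length


@dataclass
class CoverageCurve:
    """Genomic coverage as a function of sequencing depth (subsampled reads)."""

    points: pd.DataFrame  # columns: proportion, depth, coverage

    def __post_init__(self) -> None:
        cov = self.points["coverage"].to_numpy()
        if np.any(cov < 0) or np.any(cov > 1):
            raise ValueError("coverage values must lie in [0, 1]")


def coverage_curve(
    reads: ReadSet,
    genome: GenomeModel,
    ladder: Sequence[float] = SUBSAMPLE_LADDER,
    seed: int = 0,
) -> CoverageCurve:
    """Coverage at each subsampling proportion of the ladder, sorted by depth."""
    if any(not (0 < p <= 1) for p in ladder):
        raise ValueError("ladder proportions must be in (0, 1]")
    seeds = child_seeds(seed, len(ladder))
    rows = []
    for p, s in zip(ladder, seeds):
        sub = subsample_reads(reads, p, seed=s)
        rows.append((p, sub.total_reads, genomic_coverage(sub, genome)))
    df = pd.DataFrame(rows, columns=["proportion", "depth", "coverage"])
    df = df.sort_values("depth").reset_index(drop=True)
    return CoverageCurve(points=df)


# ---------------------------------------------------------------------------
# Plotting (optional, headless-safe)
# ---------------------------------------------------------------------------

def plot_correlation_heatmap(corr: CorrelationMatrix, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    order = corr.leaf_order
    mat = corr.values[np.ix_(order, order)]
    labels = corr.ordered_labels()
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(labels), 1 + 0.5 * len(labels)))
    im = ax.imshow(mat, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    fig.colorbar(im, ax=ax, label=f"{corr.method} correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coverage_curve(curve: CoverageCurve, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.points["depth"], curve.points["coverage"], marker="o")
    ax.set_xscale("log")
    ax.set_xlabel("sequencing depth (reads)")
    ax.set_ylabel("genomic coverage")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
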