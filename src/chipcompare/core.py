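"""Core data containers shared across the pipeline.

Coordinates are 0-based, half-open throughout.  A genome is partitioned into
fixed-width, non-overlapping bins; bin ``i`` of width ``b`` covers
``[i*b, (i+1)*b)`` and its centre sits at ``i*b + b/2``.  The last bin of a
chromosome may be partial but is always present, so every track covers its
chromosomes end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional

import numpy as np

__all__ = [
    "BinnedTrack",
    "GenomeModel",
    "ReadSet",
    "EnrichmentProfile",
    "MetaProfile",
    "n_bins_for",
]


def n_bins_for(length: int, bin_size: int) -> int:
    """Number of bins covering ``length`` bases (last partial bin included)."""
    return int(math.ceil(length / bin_size))


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width binned values (counts, intensities or log-ratios).

    Parameters
    ----------
    bin_size
        Bin width in base pairs.
    values
        Mapping chromosome name -> 1-D float array, one value per bin, covering
        the chromosome end to end.
    value_kind
        One of ``"count"``, ``"intensity"``, ``"log-ratio"``, ``"fraction"``.
    """

    bin_size: int
    values: Dict[str, np.ndarray]
    value_kind: str = "count"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        self.values = {c: np.asarray(v, dtype=float) for c, v in self.values.items()}

    @property
    def chroms(self) -> List[str]:
        return list(self.values)

    def n_bins(self, chrom: str) -> int:
        return len(self.values[chrom])

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_size

    def bin_centers(self, chrom: str) -> np.ndarray:
        """Genomic coordinate x_i associated with each bin (the bin centre)."""
        return self.bin_starts(chrom) + self.bin_size / 2.0

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def flat(self) -> np.ndarray:
        """Values of all chromosomes concatenated in track order."""
        return np.concatenate([self.values[c] for c in self.chroms]) if self.values else np.empty(0)

    def aligned_with(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chroms == other.chroms
            and all(self.n_bins(c) == other.n_bins(c) for c in self.chroms)
        )

    def require_aligned(self, other: "BinnedTrack") -> None:
        if not self.aligned_with(other):
            raise ValueError("binned tracks are not aligned (bin size or chromosome layout differ)")

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            bin_size=self.bin_size,
            values={c: v.copy() for c, v in self.values.items()},
            value_kind=self.value_kind,
        )

    def constant_like(self, value: float, value_kind: str = "intensity") -> "BinnedTrack":
        """A track with the same layout holding ``value`` everywhere."""
        return BinnedTrack(
            bin_size=self.bin_size,
            values={c: np.full(self.n_bins(c), float(value)) for c in self.chroms},
            value_kind=value_kind,
        )

    def aggregate(self, factor: int, how: str = "mean") -> "BinnedTrack":
        """Combine every ``factor`` adjacent bins (trailing partial group included)."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        if factor == 1:
            return self.copy()
        out = {}
        for c, v in self.values.items():
            n_out = n_bins_for(len(v), factor)
            padded = np.full(n_out * factor, np.nan)
            padded[: len(v)] = v
            grouped = padded.reshape(n_out, factor)
            with np.errstate(invalid="ignore"):
                agg = np.nanmean(grouped, axis=1) if how == "mean" else np.nansum(grouped, axis=1)
            out[c] = agg
        return BinnedTrack(bin_size=self.bin_size * factor, values=out, value_kind=self.value_kind)


@dataclass
class GenomeModel:
    """A toy multi-chromosome genome with a binned GC-fraction track."""

    chrom_names: List[str]
    chrom_lengths: Dict[str, int]
    gc_track: BinnedTrack

    def __post_init__(self) -> None:
        for c in self.chrom_names:
            L = self.chrom_lengths.get(c)
            if L is None or int(L) <= 0:
                raise ValueError(f"chromosome {c!r} must have a positive integer length")
            self.chrom_lengths[c] = int(L)
        b = self.gc_track.bin_size
        for c in self.chrom_names:
            expected = n_bins_for(self.chrom_lengths[c], b)
            if c not in self.gc_track.values:
                raise ValueError(f"gc_track missing chromosome {c!r}")
            if len(self.gc_track.values[c]) != expected:
                raise ValueError(
                    f"gc_track does not cover chromosome {c!r} end-to-end: "
                    f"{len(self.gc_track.values[c])} bins, expected {expected}"
                )
            gc = self.gc_track.values[c]
            if np.any(gc < 0) or np.any(gc > 1):
                raise ValueError(f"GC fractions outside [0, 1] on chromosome {c!r}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return n_bins_for(self.chrom_lengths[chrom], bin_size)

    def empty_track(self, bin_size: int, value: float = 0.0, value_kind: str = "count") -> BinnedTrack:
        return BinnedTrack(
            bin_size=bin_size,
            values={c: np.full(self.n_bins(c, bin_size), float(value)) for c in self.chrom_names},
            value_kind=value_kind,
        )

    def mean_gc(self) -> float:
        """Genome-wide mean GC fraction over GC-track bins."""
        return float(self.gc_track.flat().mean())


@dataclass
class ReadSet:
    """Mapped single-end reads: per-chromosome 5' positions and strands.

    ``strands[c]`` is a boolean array, ``True`` for the forward (+) strand.
    Positions are 0-based 5'-end coordinates.
    """

    read_length: int
    positions: Dict[str, np.ndarray]
    strands: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        self.positions = {c: np.asarray(p, dtype=np.int64) for c, p in self.positions.items()}
        self.strands = {c: np.asarray(s, dtype=bool) for c, s in self.strands.items()}
        for c in self.positions:
            if len(self.positions[c]) != len(self.strands[c]):
                raise ValueError(f"positions/strands length mismatch on {c!r}")

    @property
    def chroms(self) -> List[str]:
        return list(self.positions)

    @property
    def total_reads(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def validate_against(self, genome: GenomeModel) -> None:
        for c, pos in self.positions.items():
            if c not in genome.chrom_lengths:
                raise ValueError(f"reads on chromosome {c!r} absent from genome")
            if len(pos) and (pos.min() < 0 or pos.max() >= genome.chrom_lengths[c]):
                raise ValueError(f"read positions out of bounds on {c!r}")

    def copy(self) -> "ReadSet":
        return ReadSet(
            read_length=self.read_length,
            positions={c: p.copy() for c, p in self.positions.items()},
            strands={c: s.copy() for c, s in self.strands.items()},
        )


@dataclass
class EnrichmentProfile:
    """A binned log-ratio enrichment track with a per-bin usability mask.

    ``mask[c][i]`` is True where bin ``i`` is usable (covered by probes, finite,
    not excluded for high input variability).
    """

    track: BinnedTrack
    platform: str  # "chip" | "seq" | "input" | "gc" | "other"
    mask: Dict[str, np.ndarray]
    bandwidth: Optional[float] = None
    pseudocount: Optional[float] = None

    def __post_init__(self) -> None:
        self.mask = {c: np.asarray(m, dtype=bool) for c, m in self.mask.items()}
        for c in self.track.chroms:
            if c not in self.mask or len(self.mask[c]) != self.track.n_bins(c):
                raise ValueError(f"mask shape does not match track on chromosome {c!r}")
            vals = self.track.values[c]
            if not np.all(np.isfinite(vals[self.mask[c]])):
                raise ValueError(f"non-finite enrichment values on masked-in bins of {c!r}")

    @property
    def bin_size(self) -> int:
        return self.track.bin_size

    @property
    def chroms(self) -> List[str]:
        return self.track.chroms

    def masked_values(self, chrom: Optional[str] = None) -> np.ndarray:
        if chrom is not None:
            return self.track.values[chrom][self.mask[chrom]]
        return np.concatenate(
            [self.track.values[c][self.mask[c]] for c in self.chroms]
        ) if self.chroms else np.empty(0)

    def flat_mask(self) -> np.ndarray:
        return np.concatenate([self.mask[c] for c in self.chroms]) if self.chroms else np.empty(0, bool)

    def copy(self) -> "EnrichmentProfile":
        return EnrichmentProfile(
            track=self.track.copy(),
            platform=self.platform,
            mask={c: m.copy() for c, m in self.mask.items()},
            bandwidth=self.bandwidth,
            pseudocount=self.pseudocount,
        )

    @classmethod
    def from_track(cls, track: BinnedTrack, platform: str = "other",
                   mask: Optional[Dict[str, np.ndarray]] = None, **kw) -> "EnrichmentProfile":
        if mask is None:
            mask = {c: np.isfinite(track.values[c]) for c in track.chroms}
        return cls(track=track, platform=platform, mask=mask, **kw)


@dataclass
class MetaProfile:
    """Average signal in oriented windows around TSS or TES anchors.

    ``values[0]`` is the most upstream position (−flank) in the gene's own
    orientation, ``values[-1]`` the most downstream (+flank − bin).
    """

    anchor: str  # "tss" | "tes"
    values: np.ndarray
    n_sites: int
    flank: int = 2000
    bin_size: int = 50
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = 2 * self.flank // self.bin_size
        if len(self.values) != expected:
            raise ValueError(f"meta-profile has {len(self.values)} bins, expected {expected}")

    @property
    def offsets(self) -> np.ndarray:
        """Offset of each bin centre from the anchor, in bp."""
        n = len(self.values)
        return (np.arange(n) - n // 2) * self.bin_size + self.bin_size // 2
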