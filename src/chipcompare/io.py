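"""Readers and writers for the plain-text genomics formats the pipeline uses.

BED (reads, peaks, planted truth), bedGraph (binned tracks), TSV (probe
tables, correlation matrices, meta-profiles) and gene annotations as BED6 or
GFF3 gene records.  Coordinates are 0-based half-open in BED/bedGraph and
converted from GFF3's 1-based closed convention on read.  All round trips
are lossless at the written precision; values are serialized with 17
significant digits so floats survive a round trip bit for bit.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .core import BinnedTrack, GenomeModel, ReadSet
from .peaks import REGION_COLUMNS, PeakSet

__all__ = [
    "read_reads_bed",
    "write_reads_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_probes_tsv",
    "write_probes_tsv",
    "read_genes",
    "write_genes_bed",
    "read_peaks",
    "write_peaks",
    "write_truth_bed",
    "read_truth_bed",
]

FLOAT_FMT = "%.17g"


class BedFormatError(ValueError):
    pass


def _tokenize(path: Union[str, Path], min_fields: int, what: str) -> List[List[str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise BedFormatError(
                    f"{path}:{lineno}: {what} needs at least {min_fields} fields, got {len(fields)}"
                )
            rows.append([lineno] + fields)
    return rows


def _parse_interval(path, lineno: int, start_s: str, end_s: str) -> tuple:
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
    if start < 0 or end <= start:
        raise BedFormatError(
            f"{path}:{lineno}: invalid interval [{start}, {end}) — need 0 <= start < end"
        )
    return start, end


# ---------------------------------------------------------------------------
# Reads as BED6
# ---------------------------------------------------------------------------

def write_reads_bed(reads: ReadSet, path: Union[str, Path]) -> None:
    """6-column BED, one line per read: chrom, 5'pos, 5'pos+read_len, '.', 0, strand."""
    with open(path, "w") as fh:
        for c in reads.chroms:
            pos = reads.positions[c]
            strands = reads.strands[c]
            for p, fwd in zip(pos, strands):
                fh.write(f"{c}\t{p}\t{p + reads.read_length}\t.\t0\t{'+' if fwd else '-'}\n")


def read_reads_bed(path: Union[str, Path], read_length: Optional[int] = None) -> ReadSet:
    """Read mapped-read positions from BED6 (start = 5' position for + reads).

    For − strand reads the stored 5' position is the interval start as well:
    the simulator and all binning operate on the BED start coordinate, and
    the strand column drives shifting only.
    """
    rows = _tokenize(path, 6, "read BED")
    positions: Dict[str, List[int]] = {}
    strands: Dict[str, List[bool]] = {}
    length = read_length
    for lineno, *fields in rows:
        chrom, start_s, end_s, _name, _score, strand = fields[:6]
        start, end = _parse_interval(path, lineno, start_s, end_s)
        if strand not in ("+", "-"):
            raise BedFormatError(f"{path}:{lineno}: strand must be '+' or '-', got {strand!r}")
        if length is None:
            length = end - start
        positions.setdefault(chrom, []).append(start)
        strands.setdefault(chrom, []).append(strand == "+")
    if length is None:
        length = 36
    return ReadSet(
        read_length=length,
        positions={c: np.array(v, dtype=np.int64) for c, v in positions.items()},
        strands={c: np.array(v, dtype=bool) for c, v in strands.items()},
    )


# ---------------------------------------------------------------------------
# Binned tracks as bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: BinnedTrack, path: Union[str, Path],
                   genome: Optional[GenomeModel] = None) -> None:
    """One line per bin; the last bin is truncated at the chromosome end if known."""
    with open(path, "w") as fh:
        for c in track.chroms:
            starts = track.bin_starts(c)
            ends = starts + track.bin_size
            if genome is not None:
                ends = np.minimum(ends, genome.chrom_lengths[c])
            for s, e, v in zip(starts, ends, track.values[c]):
                fh.write(f"{c}\t{s}\t{e}\t{FLOAT_FMT % v}\n")


def read_bedgraph(path: Union[str, Path], value_kind: str = "intensity") -> BinnedTrack:
    """Read a constant-step bedGraph back into a BinnedTrack.

    The step of the first interval defines the bin size; a differing step
    anywhere (except a truncated final bin per chromosome) is an error.
    """
    rows = _tokenize(path, 4, "bedGraph")
    per_chrom: Dict[str, List[tuple]] = {}
    for lineno, *fields in rows:
        chrom, start_s, end_s, val_s = fields[:4]
        start, end = _parse_interval(path, lineno, start_s, end_s)
        try:
            val = float(val_s)
        except ValueError as exc:
            raise BedFormatError(f"{path}:{lineno}: non-numeric value {val_s!r}") from exc
        per_chrom.setdefault(chrom, []).append((lineno, start, end, val))
    if not per_chrom:
        raise BedFormatError(f"{path}: empty bedGraph")
    bin_size = None
    values: Dict[str, np.ndarray] = {}
    for chrom, entries in per_chrom.items():
        entries.sort(key=lambda t: t[1])
        vals = []
        for i, (lineno, start, end, val) in enumerate(entries):
            step = end - start
            if bin_size is None:
                bin_size = step
            if start != i * bin_size:
                raise BedFormatError(
                    f"{path}:{lineno}: non-constant step on {chrom!r} "
                    f"(expected start {i * bin_size}, got {start})"
                )
            if step > bin_size or (step < bin_size and i != len(entries) - 1):
                raise BedFormatError(f"{path}:{lineno}: non-constant step size on {chrom!r}")
            vals.append(val)
        values[chrom] = np.array(vals)
    return BinnedTrack(bin_size=int(bin_size), values=values, value_kind=value_kind)


# ---------------------------------------------------------------------------
# Probe tables
# ---------------------------------------------------------------------------

PROBE_COLUMNS = ["chrom", "start", "end", "probe_id", "ip_intensity", "input_intensity"]


def write_probes_tsv(probes: pd.DataFrame, path: Union[str, Path]) -> None:
    probes.to_csv(path, sep="\t", index=False, columns=PROBE_COLUMNS, float_format=FLOAT_FMT)


def read_probes_tsv(path: Union[str, Path]) -> pd.DataFrame:
    probes = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise BedFormatError(f"{path}: probe table missing columns {missing}")
    if (probes["ip_intensity"] <= 0).any() or (probes["input_intensity"] <= 0).any():
        raise BedFormatError(f"{path}: probe intensities must be strictly positive")
    return probes.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gene annotations
# ---------------------------------------------------------------------------

def write_genes_bed(genes: pd.DataFrame, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.gene_id}\t0\t{row.strand}\n")


def _read_genes_gff3(path: Union[str, Path]) -> pd.DataFrame:
    rows = _tokenize(path, 9, "GFF3")
    out = []
    for lineno, *fields in rows:
        chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
        if feature != "gene":
            continue
        try:
            start1, end1 = int(start_s), int(end_s)
        except ValueError as exc:
            raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if strand not in ("+", "-"):
            raise BedFormatError(f"{path}:{lineno}: strand must be '+' or '-'")
        gene_id = f"gene_line{lineno}"
        for part in attrs.split(";"):
            key, _, val = part.partition("=")
            if key.strip() == "ID":
                gene_id = val.strip()
        out.append((chrom, start1 - 1, end1, strand, gene_id))  # GFF3 is 1-based closed
    return pd.DataFrame(out, columns=["chrom", "start", "end", "strand", "gene_id"])


def read_genes(path: Union[str, Path]) -> pd.DataFrame:
    """Read gene models from BED6 or GFF3 (by extension)."""
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        genes = _read_genes_gff3(path)
    else:
        rows = _tokenize(path, 6, "gene BED")
        out = []
        for lineno, *fields in rows:
            chrom, start_s, end_s, gene_id, _score, strand = fields[:6]
            start, end = _parse_interval(path, lineno, start_s, end_s)
            if strand not in ("+", "-"):
                raise BedFormatError(f"{path}:{lineno}: strand must be '+' or '-'")
            out.append((chrom, start, end, strand, gene_id))
        genes = pd.DataFrame(out, columns=["chrom", "start", "end", "strand", "gene_id"])
    return genes.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Peak sets
# ---------------------------------------------------------------------------

def write_peaks(peaks: PeakSet, path: Union[str, Path]) -> None:
    """BED6+4: chrom, start, end, id, −10·log10(p) score, '.', m, l, p, q, significant."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tm\tl\tp\tq\tsignificant\n")
        fh.write(f"#bin_size={peaks.bin_size}\tk={FLOAT_FMT % peaks.k}\tfdr={FLOAT_FMT % peaks.fdr}\n")
        for i, row in enumerate(peaks.regions.itertuples(index=False)):
            score = min(1000, int(round(-10 * np.log10(max(row.p, 1e-300)))))
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\tpeak_{i}\t{score}\t.\t"
                f"{row.m}\t{FLOAT_FMT % row.l}\t{FLOAT_FMT % row.p}\t{FLOAT_FMT % row.q}\t"
                f"{int(row.significant)}\n"
            )


def read_peaks(path: Union[str, Path]) -> PeakSet:
    meta = {"bin_size": 50, "k": 0.0, "fdr": 0.05}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#bin_size="):
                for part in line.lstrip("#").split("\t"):
                    key, _, val = part.strip().partition("=")
                    meta[key] = float(val)
    rows = _tokenize(path, 11, "peak BED")
    out = []
    for lineno, *fields in rows:
        chrom, start_s, end_s = fields[0], fields[1], fields[2]
        start, end = _parse_interval(path, lineno, start_s, end_s)
        m, l, p, q, sig = int(fields[6]), float(fields[7]), float(fields[8]), float(fields[9]), fields[10]
        out.append((chrom, start, end, m, l, p, q, bool(int(sig))))
    regions = pd.DataFrame(out, columns=REGION_COLUMNS)
    regions = regions.sort_values(["chrom", "start"]).reset_index(drop=True)
    return PeakSet(regions=regions, bin_size=int(meta["bin_size"]),
                   k=float(meta["k"]), fdr=float(meta["fdr"]))


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

def write_truth_bed(truth: pd.DataFrame, path: Union[str, Path]) -> None:
    """Planted regions as BED with the effect multiplier in the score column."""
    with open(path, "w") as fh:
        for row in truth.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.width_class}\t"
                     f"{FLOAT_FMT % row.effect}\t.\n")


def read_truth_bed(path: Union[str, Path]) -> pd.DataFrame:
    rows = _tokenize(path, 6, "truth BED")
    out = []
    for lineno, *fields in rows:
        chrom, start_s, end_s, cls, eff_s, _ = fields[:6]
        start, end = _parse_interval(path, lineno, start_s, end_s)
        out.append((chrom, start, end, float(eff_s), cls))
    df = pd.DataFrame(out, columns=["chrom", "start", "end", "effect", "width_class"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)
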