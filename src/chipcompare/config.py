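"""Validated run configuration for the end-to-end synthetic experiment."""

from __future__ import annotations

from typing import List, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .synthetic import SUBSAMPLE_LADDER

__all__ = ["RunConfig", "demo_config", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenomeConfig(_Strict):
    n_chrom: int = Field(2, ge=1)
    chrom_length: int = Field(500_000, ge=10_000)
    gc_mean: float = Field(0.42, gt=0, lt=1)
    gc_amplitude: float = Field(0.10, ge=0, lt=0.5)
    gc_scale: int = Field(10_000, gt=0)
    bin_size: int = Field(50, gt=0)


class RegionsConfig(_Strict):
    n_regions: int = Field(50, ge=0)
    narrow_width: Tuple[int, int] = (500, 1000)
    broad_width: Tuple[int, int] = (3000, 8000)
    narrow_fraction: float = Field(0.5, ge=0, le=1)
    effect_min: float = Field(4.0, gt=1)
    effect_max: float = Field(8.0, gt=1)
    min_gap: int = Field(1000, ge=0)

    @model_validator(mode="after")
    def _ranges(self) -> "RegionsConfig":
        if self.effect_max < self.effect_min:
            raise ValueError("effect_max must be >= effect_min")
        return self


class ReadsConfig(_Strict):
    chip_depth: int = Field(500_000, gt=0)
    input_depth: int = Field(500_000, gt=0)
    gc_beta: float = 0.0
    input_gc_beta: float = 2.0
    frag_len: int = Field(200, gt=0)
    read_len: int = Field(36, gt=0)

    @model_validator(mode="after")
    def _frag(self) -> "ReadsConfig":
        if self.frag_len < self.read_len:
            raise ValueError("frag_len must be >= read_len")
        return self


class ArrayConfig(_Strict):
    probe_spacing: int = Field(50, gt=0)
    coverage_target: float = Field(0.7, gt=0, le=1)
    noise_sd: float = Field(0.4, ge=0)
    mean_dropout_block: float = Field(5000.0, gt=0)


class ProfileConfig(_Strict):
    bin_size: int = Field(50, gt=0)
    bandwidth: float = Field(50.0, gt=0)
    max_neighbors: int = Field(400, gt=0)
    pseudocount: float = Field(0.5, gt=0)
    aggregate: int = Field(20, ge=1)


class PeaksConfig(_Strict):
    k: float = 0.0
    fdr: float = Field(0.05, gt=0, lt=1)
    top_n: int = Field(1000, ge=1)


class QcConfig(_Strict):
    ladder: List[float] = Field(default_factory=lambda: list(SUBSAMPLE_LADDER))
    trim: float = Field(0.05, ge=0, lt=0.5)
    variability_quantile: float = Field(0.95, gt=0, lt=1)

    @model_validator(mode="after")
    def _ladder(self) -> "QcConfig":
        if any(not (0 < p <= 1) for p in self.ladder):
            raise ValueError("ladder proportions must be in (0, 1]")
        return self


class GenesConfig(_Strict):
    n_genes: int = Field(150, ge=0)
    min_length: int = Field(800, gt=0)
    max_length: int = Field(8000, gt=0)
    min_gene_length: int = Field(2000, gt=0)  # meta-profile filter
    flank: int = Field(2000, gt=0)


class RunConfig(_Strict):
    """Hierarchical parameters for ``run_experiment``; unknown keys are rejected."""

    seed: int = 0
    genome: GenomeConfig = Field(default_factory=GenomeConfig)
    regions: RegionsConfig = Field(default_factory=RegionsConfig)
    reads: ReadsConfig = Field(default_factory=ReadsConfig)
    array: ArrayConfig = Field(default_factory=ArrayConfig)
    profile: ProfileConfig = Field(default_factory=ProfileConfig)
    peaks: PeaksConfig = Field(default_factory=PeaksConfig)
    qc: QcConfig = Field(default_factory=QcConfig)
    genes: GenesConfig = Field(default_factory=GenesConfig)
    make_figures: bool = False


def demo_config(seed: int = 0) -> RunConfig:
    """The shipped demo: defaults throughout (bin 50, bandwidth 50, aggregate 20,
    k 0, FDR 0.05, the full subsampling ladder, 2 kb flanks and gene filter)."""
    return RunConfig(seed=seed)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)
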