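"""Pipeline configuration.

All numeric thresholds used by the pipeline live here and only here; stage
code receives a :class:`PipelineConfig` and never hard-codes a cutoff. The
defaults reproduce the study design this package models: 100-bp genomic
windows, removal of windows with fewer than 40 reads summed across samples,
region seeding at p < 1e-6 with edge extension while any window at p < 0.1
lies within 1000 bp, 300-bp sonicated fragments, 10-kb gene proximity and
100-kb multi-mark co-localization.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from typing import Any, Mapping


@dataclass
class PipelineConfig:
    """Thresholds and sizes shared by every pipeline stage.

    Parameters
    ----------
    window_size:
        Genomic window width in bp used to tile the reference.
    min_total_reads:
        A window is removed when its count summed across all samples is
        strictly below this value.
    seed_p:
        Per-window p-value below which a window seeds a region (DMR/DHR).
    extension_p:
        Region edges extend while a retained window with p below this value
        lies within ``extension_gap`` of the region boundary.
    extension_gap:
        Edge-to-edge distance (bp) within which sub-threshold windows are
        absorbed during region extension.
    fragment_length:
        Assumed sonication fragment size (bp); single-end reads are extended
        to this length before midpoint assignment.
    gene_proximity:
        Maximum edge-to-edge distance (bp) for a region-gene association.
    coloc_window:
        Span (bp) used when co-localizing epimutations of different kinds.
    fdr_alpha:
        Benjamini-Hochberg FDR level reported alongside raw-p region calls.
    rng_seed:
        Seed for every stochastic stage (simulation, Monte-Carlo permutation).
    """

    window_size: int = 100
    min_total_reads: int = 40
    seed_p: float = 1e-6
    extension_p: float = 0.1
    extension_gap: int = 1000
    fragment_length: int = 300
    gene_proximity: int = 10_000
    coloc_window: int = 100_000
    fdr_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.seed_p < self.extension_p <= 1.0):
            raise ValueError(
                f"require 0 < seed_p < extension_p <= 1, got "
                f"seed_p={self.seed_p}, extension_p={self.extension_p}"
            )
        for name in ("window_size", "extension_gap", "fragment_length",
                     "gene_proximity", "coloc_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_total_reads < 0:
            raise ValueError("min_total_reads must be >= 0")
        if not (0.0 < self.fdr_alpha <= 1.0):
            raise ValueError("fdr_alpha must be in (0, 1]")

    def replace(self, **overrides: Any) -> "PipelineConfig":
        d = asdict(self)
        d.update(overrides)
        return PipelineConfig(**d)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        """Build a config from a flat key:value mapping (e.g. a YAML file).

        Unknown keys raise ``KeyError`` so typos in config files fail loudly.
        """
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))
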