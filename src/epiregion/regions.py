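"""DMR/DHR calling: seed windows, edge extension, merging, features.

A window with p below the seed threshold starts a region; region edges are
extended while any retained window with p below the extension threshold
lies within the extension gap (edge-to-edge, distance 0 when overlapping
or adjacent) of the current boundary, absorbing every intervening window
regardless of its p. Extension iterates to closure, so regions whose
closures meet merge into one and the result is independent of processing
order. Because the boundary moves as windows are absorbed, the closure
chains transitively: the final regions are exactly the single-linkage
chains (at the extension gap) of sub-threshold windows that contain at
least one seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .difftest import WindowTestResult
from .genome import GenomeIndex, cpg_features


@dataclass
class EpiRegion:
    """A called differential region (DMR or DHR)."""

    chrom: str
    start: int
    end: int  # half-open
    n_windows_total: int
    n_significant_windows: int
    min_p: float
    max_abs_log2fc: float
    cpg_count: int | None = None
    cpg_density: float | None = None  # CpG per 100 bp
    length_kb_bin: int | None = None  # ceil(length / 1000)
    region_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")
        if self.n_significant_windows < 1:
            raise ValueError("a region must contain at least one significant window")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class RegionSet:
    """Disjoint, sorted regions of one mark (DMR / DHR / H3K27me3-DHR)."""

    regions: list[EpiRegion]
    mark: str = "DMR"
    generation: str = "F1"
    seed_p: float = 1e-6
    extension_p: float = 0.1
    extension_gap: int = 1000

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def intervals(self) -> list[tuple[str, int, int]]:
        return [(r.chrom, r.start, r.end) for r in self.regions]

    def to_bed(self, path: str | Path) -> None:
        """BED6: score = min(1000, round(-10*log10(min_p)))."""
        with open(path, "w") as fh:
            for r in self.regions:
                score = 1000 if r.min_p <= 0 else min(1000, round(-10 * math.log10(r.min_p)))
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{score}\t.\n")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": [r.region_id for r in self.regions],
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "stop": [r.end for r in self.regions],
                "length": [r.length for r in self.regions],
                "n_windows_total": [r.n_windows_total for r in self.regions],
                "n_significant_windows": [r.n_significant_windows for r in self.regions],
                "min_p": [r.min_p for r in self.regions],
                "cpg_count": [r.cpg_count for r in self.regions],
                "cpg_density": [r.cpg_density for r in self.regions],
            }
        )

    def to_tsv(self, path: str | Path, gene_associations: pd.DataFrame | None = None) -> None:
        df = self.to_frame()
        if gene_associations is not None and len(gene_associations):
            assoc = (
                gene_associations.groupby("region_id")["gene_name"]
                .apply(lambda s: ";".join(sorted(set(s))))
                .rename("gene_association")
            )
            df = df.merge(assoc, on="region_id", how="left")
        else:
            df["gene_association"] = None
        df["gene_association"] = df["gene_association"].fillna("intergenic")
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def call_regions(
    test_result: WindowTestResult,
    config: PipelineConfig,
    mark: str = "DMR",
    generation: str = "F1",
) -> RegionSet:
    """Seed-extend-merge region calling on the retained windows.

    ``test_result`` covers exactly the retained (post-filter) windows;
    filtered-out windows are invisible to extension, though their genomic
    span may be absorbed as intervening sequence since a region is reported
    as one contiguous interval.
    """
    if not (config.seed_p < config.extension_p):
        raise ValueError("seed_p must be < extension_p")
    windows = test_result.windows
    p = np.asarray(test_result.p_value)
    lfc = np.asarray(test_result.log2_fold_change)

    regions: list[EpiRegion] = []
    # windows are in genome order; process each chromosome's run
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)

    for chrom, rows in by_chrom.items():
        rows.sort(key=lambda i: windows[i].start)
        cand = [i for i in rows if p[i] < config.extension_p]
        if not cand:
            continue
        # single-linkage chains of sub-threshold windows at the extension gap
        chains: list[list[int]] = [[cand[0]]]
        for i in cand[1:]:
            gap = windows[i].start - windows[chains[-1][-1]].end
            if gap <= config.extension_gap:
                chains[-1].append(i)
            else:
                chains.append([i])
        for chain in chains:
            seeds = [i for i in chain if p[i] < config.seed_p]
            if not seeds:
                continue
            start = windows[chain[0]].start
            end = windows[chain[-1]].end
            inside = [i for i in rows if windows[i].start < end and windows[i].end > start]
            regions.append(
                EpiRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_windows_total=len(inside),
                    n_significant_windows=len(seeds),
                    min_p=float(p[seeds].min() if len(seeds) > 1 else p[seeds[0]]),
                    max_abs_log2fc=float(np.abs(lfc[inside]).max()),
                    region_id=f"{mark}:{chrom}:{start}-{end}",
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return RegionSet(
        regions,
        mark=mark,
        generation=generation,
        seed_p=config.seed_p,
        extension_p=config.extension_p,
        extension_gap=config.extension_gap,
    )


def classify_regions(region_set: RegionSet) -> dict[str, int]:
    """All-window vs multiple-window counts.

    A multiple-window region contains at least two windows individually
    below the seed threshold.
    """
    all_window = len(region_set.regions)
    multiple = sum(1 for r in region_set.regions if r.n_significant_windows >= 2)
    return {"all_window": all_window, "multiple_window": multiple}


def threshold_ladder(
    test_result: WindowTestResult,
    config: PipelineConfig,
    thresholds: list[float] | None = None,
    mark: str = "DMR",
) -> pd.DataFrame:
    """Region counts at a ladder of seed thresholds (1e-4 ... 1e-8 style)."""
    thresholds = thresholds or [1e-4, 1e-5, 1e-6, 1e-7, 1e-8]
    rows = []
    for thr in sorted(thresholds, reverse=True):
        rs = call_regions(test_result, config.replace(seed_p=thr), mark=mark)
        counts = classify_regions(rs)
        rows.append({"seed_p": thr, **counts})
    return pd.DataFrame(rows)


def annotate_features(region_set: RegionSet, genome: GenomeIndex) -> RegionSet:
    """Fill CpG count/density and length bin from the reference sequence."""
    annotated = []
    for r in region_set.regions:
        count, density = cpg_features(genome, r.chrom, r.start, r.end)
        annotated.append(
            replace(
                r,
                cpg_count=count,
                cpg_density=density,
                length_kb_bin=math.ceil(r.length / 1000),
            )
        )
    return replace_regions(region_set, annotated)


def replace_regions(region_set: RegionSet, regions: list[EpiRegion]) -> RegionSet:
    rs = RegionSet(
        regions,
        mark=region_set.mark,
        generation=region_set.generation,
        seed_p=region_set.seed_p,
        extension_p=region_set.extension_p,
        extension_gap=region_set.extension_gap,
    )
    return rs


def feature_histograms(region_set: RegionSet) -> dict[str, pd.DataFrame]:
    """Histogram tables of CpG density (per 100 bp, integer bins, half-up
    rounding) and length (kb, ceiling bins) across a region set."""
    dens = [r.cpg_density for r in region_set.regions if r.cpg_density is not None]
    lens = [r.length_kb_bin for r in region_set.regions if r.length_kb_bin is not None]
    density_bins = [int(math.floor(d + 0.5)) for d in dens]
    density_df = (
        pd.Series(density_bins, dtype=int).value_counts().sort_index().rename_axis(
            "cpg_per_100bp").reset_index(name="n_regions")
    )
    length_df = (
        pd.Series(lens, dtype=int).value_counts().sort_index().rename_axis(
            "length_kb").reset_index(name="n_regions")
    )
    return {"cpg_density": density_df, "length_kb": length_df}
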