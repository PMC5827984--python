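"""Synthetic inputs with planted truth for the whole pipeline.

The generator emulates the study conditions this package models: a 3-vs-3
pooled two-lineage design; per-window fragment counts that are negative-
binomially distributed across replicate pools (Var = mu + phi mu^2, the
same parameterization the test uses); planted multi-window differential
regions at a stated fold change; CpG-desert sequence structure at ~1 CpG
per 100 bp; and toy gene/ncRNA annotations. Every generator is
deterministic under its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import SampleDesign, WindowCountMatrix
from .genome import GenomeIndex, Window, build_windows
from .integrate import NCRNA_CLASSES


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start_window: int  # window ordinal within the chromosome
    n_windows: int
    fold_change: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.n_windows < 1:
            raise ValueError("n_windows must be >= 1")


@dataclass
class SimulationSpec:
    """Study-condition parameters for the synthetic pipeline inputs.

    Defaults give the standard benchmark grid: 5 chromosomes x 1 Mb =
    50,000 windows of 100 bp; baseline mean 50 fragments per window per
    pool; dispersion 0.1; 3 pools per lineage; CpG rate 1 per 100 bp
    (CpG-desert structure).
    """

    n_chromosomes: int = 5
    chrom_length: int = 1_000_000
    window_size: int = 100
    cpg_rate: float = 1.0  # CpG per 100 bp
    n_samples_per_group: int = 3
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.cpg_rate < 0:
            raise ValueError("cpg_rate must be >= 0")
        if self.chrom_length < self.window_size:
            raise ValueError("chrom_length must be >= window_size")
        self._check_planted_disjoint()

    def _check_planted_disjoint(self) -> None:
        spans = sorted(
            (p.chrom, p.start_window, p.start_window + p.n_windows)
            for p in self.planted_regions
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("planted regions must be non-overlapping")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class SyntheticTruth:
    """Planted-region intervals plus per-window true means per group."""

    planted_intervals: list[tuple[str, int, int]]  # bp coordinates
    true_mean_control: np.ndarray
    true_mean_exposed: np.ndarray
    spec: SimulationSpec

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.planted_intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.spec.to_dict(), indent=2))


def default_planted_regions(
    spec: SimulationSpec,
    n_regions: int = 100,
    n_windows: int = 3,
    fold_change: float = 4.0,
    rng: np.random.Generator | None = None,
) -> list[PlantedRegion]:
    """Place non-overlapping multi-window regions uniformly on the grid.

    Regions are separated by at least one window so calls cannot merge
    across distinct truths by adjacency alone.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    windows_per_chrom = -(-spec.chrom_length // spec.window_size)
    placed: list[PlantedRegion] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chrom_names}
    attempts = 0
    while len(placed) < n_regions:
        attempts += 1
        if attempts > 100 * n_regions:
            raise RuntimeError("could not place non-overlapping planted regions")
        chrom = spec.chrom_names[int(rng.integers(spec.n_chromosomes))]
        start = int(rng.integers(0, windows_per_chrom - n_windows))
        # enforce a >= 20-window buffer so neighboring truths stay distinct
        if any(start < e + 20 and start + n_windows + 20 > s for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, start + n_windows))
        placed.append(PlantedRegion(chrom, start, n_windows, fold_change))
    placed.sort(key=lambda p: (p.chrom, p.start_window))
    return placed


def simulate_genome(spec: SimulationSpec, fasta_path: str | Path | None = None) -> GenomeIndex:
    """CpG-desert genome: A/T background with CG dinucleotides at Poisson
    rate ``cpg_rate`` per 100 bp.

    Placing whole CG dinucleotides on a C/G-free background makes the
    realized CpG rate exactly the planted one (no accidental CG can arise)
    while keeping the sequence A/T-rich, the salient property of the
    CpG-desert regions this emulates.
    """
    rng = np.random.default_rng(spec.rng_seed)
    seqs: dict[str, str] = {}
    for chrom in spec.chrom_names:
        length = spec.chrom_length
        arr = rng.choice(np.frombuffer(b"AT", dtype="S1"), size=length)
        n_cpg = rng.poisson(length * spec.cpg_rate / 100.0)
        if n_cpg > 0 and length >= 2:
            positions = np.sort(rng.integers(0, length - 1, size=n_cpg))
            # drop placements that would overlap the previous CG
            keep = np.ones(len(positions), dtype=bool)
            last = -2
            for i, pos in enumerate(positions):
                if pos - last < 2:
                    keep[i] = False
                else:
                    last = pos
            positions = positions[keep]
            arr[positions] = b"C"
            arr[positions + 1] = b"G"
        seqs[chrom] = arr.tobytes().decode("ascii")
    genome = GenomeIndex(seqs)
    if fasta_path is not None:
        genome.to_fasta(fasta_path)
    return genome


def simulate_counts(
    spec: SimulationSpec, windows: list[Window]
) -> tuple[WindowCountMatrix, SyntheticTruth]:
    """NB count matrix with planted differential regions.

    count[w, s] ~ NB(mean = mu * f(w, s), dispersion phi) independently,
    where f = fold_change inside planted regions for exposed samples and 1
    elsewhere.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    n_w = len(windows)
    n_per = spec.n_samples_per_group
    design = SampleDesign.balanced(n_per)

    row_of: dict[tuple[str, int], int] = {(w.chrom, w.index): i for i, w in enumerate(windows)}
    fold = np.ones(n_w)
    intervals: list[tuple[str, int, int]] = []
    for region in spec.planted_regions:
        rows = []
        for k in range(region.n_windows):
            key = (region.chrom, region.start_window + k)
            if key not in row_of:
                raise ValueError(f"planted region {region} outside the window grid")
            rows.append(row_of[key])
        fold[rows] = region.fold_change
        intervals.append(
            (region.chrom, windows[rows[0]].start, windows[rows[-1]].end)
        )

    mean_control = np.full(n_w, spec.baseline_mean)
    mean_exposed = spec.baseline_mean * fold
    means = np.column_stack([mean_control] * n_per + [mean_exposed] * n_per)

    if spec.dispersion == 0:
        counts = rng.poisson(means)
    else:
        r = 1.0 / spec.dispersion
        p = r / (r + means)
        counts = rng.negative_binomial(r, p)
    matrix = WindowCountMatrix(windows, counts, design, counts.sum(axis=0))
    truth = SyntheticTruth(intervals, mean_control, mean_exposed, spec)
    return matrix, truth


def simulate_fragment_bed(
    column: np.ndarray,
    windows: list[Window],
    path: str | Path,
    fragment_length: int = 300,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Emit one sample's counts as sorted BED fragments.

    Each window emits as many fragments as its count, with midpoints
    uniform within the window, so midpoint counting reproduces the column
    exactly.
    """
    rng = np.random.default_rng(seed)
    half = fragment_length // 2
    with open(path, "w") as fh:
        for w, c in zip(windows, column):
            if c == 0:
                continue
            mids = np.sort(rng.integers(w.start, w.end, size=int(c)))
            limit = chrom_lengths[w.chrom] if chrom_lengths is not None else None
            for mid in mids:
                mid = int(mid)
                start = max(0, mid - half)
                end = 2 * mid - start  # keeps floor((start+end)/2) == mid
                if limit is not None and end > limit:
                    end = limit
                    start = 2 * mid - end
                fh.write(f"{w.chrom}\t{start}\t{end}\n")


def simulate_gene_annotation(
    genome: GenomeIndex, n_genes: int = 50, seed: int = 0,
    gff_path: str | Path | None = None, gene_length: int = 20_000,
) -> pd.DataFrame:
    """Toy gene annotation: non-overlapping spans uniform on the genome.

    Returns a frame with 0-based half-open coordinates; optionally writes
    GFF3 (1-based inclusive).
    """
    rng = np.random.default_rng(seed)
    rows = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in genome.chromosomes}
    attempts = 0
    while len(rows) < n_genes:
        attempts += 1
        if attempts > 200 * n_genes:
            break
        chrom, length = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
        if length <= gene_length:
            continue
        start = int(rng.integers(0, length - gene_length))
        end = start + gene_length
        if any(start < e and end > s for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        gid = f"G{len(rows) + 1:04d}"
        rows.append(
            {"gene_id": gid, "gene_name": f"Gene{len(rows) + 1}",
             "chrom": chrom, "start": start, "end": end,
             "strand": "+" if rng.random() < 0.5 else "-"}
        )
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    if gff_path is not None:
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            for _, g in df.iterrows():
                fh.write(
                    f"{g.chrom}\tepiregion_sim\tgene\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id};Name={g.gene_name}\n"
                )
    return df


def simulate_ncrna_table(
    genome: GenomeIndex,
    n_rows: int = 200,
    class_probs: dict[str, float] | None = None,
    signal_fraction: float = 0.2,
    signal_p_scale: float = 1e-6,
    unknown_location_fraction: float = 0.02,
    generation: str = "F1",
    seed: int = 0,
    feature_length: int = 1000,
) -> pd.DataFrame:
    """Differential-ncRNA table: named features with classes and p-values.

    A ``signal_fraction`` of rows get exponentially small p-values (scale
    ``signal_p_scale``, far below the 1e-4 integration threshold); the rest
    are uniform nulls. A configurable fraction has unknown chromosome
    location (empty chrom), mirroring real tables.
    """
    if class_probs is None:
        class_probs = {"miRNA": 0.1, "piRNA": 0.45, "stRNA": 0.25,
                       "lncRNA": 0.1, "other": 0.1}
    unknown = set(class_probs) - set(NCRNA_CLASSES)
    if unknown:
        raise ValueError(f"unknown ncRNA classes {sorted(unknown)}")
    total = sum(class_probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    rng = np.random.default_rng(seed)
    classes = rng.choice(list(class_probs), size=n_rows, p=list(class_probs.values()))
    is_signal = rng.random(n_rows) < signal_fraction
    p_values = np.where(
        is_signal,
        np.minimum(rng.exponential(signal_p_scale, size=n_rows), 1.0),
        rng.random(n_rows),
    )
    chroms, starts, ends = [], [], []
    names = []
    for i in range(n_rows):
        names.append(f"{classes[i]}-{generation}-{i + 1:04d}")
        if rng.random() < unknown_location_fraction:
            chroms.append("")
            starts.append(-1)
            ends.append(-1)
        else:
            chrom, length = genome.chromosomes[int(rng.integers(len(genome.chromosomes)))]
            start = int(rng.integers(0, max(1, length - feature_length)))
            chroms.append(chrom)
            starts.append(start)
            ends.append(start + feature_length)
    return pd.DataFrame(
        {
            "name": names,
            "class": classes,
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "p_value": p_values,
            "generation": generation,
        }
    )


def simulate_windows(spec: SimulationSpec, genome: GenomeIndex | None = None) -> list[Window]:
    """Window grid for the spec (building the genome when not supplied)."""
    genome = genome or simulate_genome(spec)
    return build_windows(genome, spec.window_size)
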