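"""Per-window fragment counting and the low-coverage filter.

Each usable fragment contributes exactly one count, to the window containing
its midpoint. Single-end reads are extended to the configured fragment
length from the 5' end in the strand direction before taking the midpoint;
properly paired reads use the pair span. The midpoint of an even-length
fragment is ``floor((start + end) / 2)``; a midpoint landing exactly on a
window boundary belongs to the right window (half-open convention).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .genome import Window

CONTROL = "control"
EXPOSED = "exposed"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    group: str  # "control" | "exposed"
    alignment_path: str | None = None

    def __post_init__(self) -> None:
        if self.group not in (CONTROL, EXPOSED):
            raise ValueError(f"group must be {CONTROL!r} or {EXPOSED!r}, got {self.group!r}")


@dataclass
class SampleDesign:
    """Two-lineage pooled design: ordered samples with group labels."""

    samples: list[Sample]
    generation: str = "F1"

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        for grp in (CONTROL, EXPOSED):
            if sum(s.group == grp for s in self.samples) < 2:
                raise ValueError(f"need >=2 samples in group {grp!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def groups(self) -> list[str]:
        return [s.group for s in self.samples]

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.samples) if s.group == group])

    def relabel(self, control_indices: Sequence[int]) -> "SampleDesign":
        """Return a design with the given sample indices labelled control."""
        ctrl = set(control_indices)
        samples = [
            Sample(s.sample_id, CONTROL if i in ctrl else EXPOSED, s.alignment_path)
            for i, s in enumerate(self.samples)
        ]
        return SampleDesign(samples, generation=self.generation)

    @classmethod
    def balanced(cls, n_per_group: int, generation: str = "F1") -> "SampleDesign":
        samples = [Sample(f"control_{i + 1}", CONTROL) for i in range(n_per_group)]
        samples += [Sample(f"exposed_{i + 1}", EXPOSED) for i in range(n_per_group)]
        return cls(samples, generation=generation)


@dataclass
class CountingStats:
    """Bookkeeping from one alignment pass."""

    usable: int = 0
    skipped_flagged: int = 0  # unmapped/secondary/supplementary/duplicate
    unresolved_chroms: dict[str, int] = field(default_factory=dict)


@dataclass
class WindowCountMatrix:
    """Per-window x per-sample fragment counts, the pipeline's central table.

    ``library_sizes`` are the total assigned fragments per sample at
    construction; they are deliberately NOT recomputed after window
    filtering.
    """

    windows: list[Window]
    counts: np.ndarray  # (n_windows, n_samples) int64
    design: SampleDesign
    library_sizes: np.ndarray  # (n_samples,) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.counts.shape != (len(self.windows), len(self.design.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.windows)} windows x {len(self.design.samples)} samples"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_samples(self) -> int:
        return len(self.design.samples)

    def to_tsv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Persist as TSV (coords + one column per sample) with JSON sidecar."""
        df = pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
            }
        )
        for j, sid in enumerate(self.design.sample_ids):
            df[sid] = self.counts[:, j]
        df.to_csv(path, sep="\t", index=False)
        if sidecar is not None:
            meta = {
                "samples": [
                    {"sample_id": s.sample_id, "group": s.group,
                     "alignment_path": s.alignment_path}
                    for s in self.design.samples
                ],
                "generation": self.design.generation,
                "library_sizes": self.library_sizes.tolist(),
            }
            Path(sidecar).write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path, sidecar: str | Path) -> "WindowCountMatrix":
        df = pd.read_csv(path, sep="\t")
        meta = json.loads(Path(sidecar).read_text())
        design = SampleDesign(
            [Sample(s["sample_id"], s["group"], s.get("alignment_path"))
             for s in meta["samples"]],
            generation=meta.get("generation", "F1"),
        )
        windows = _windows_from_coords(df["chrom"], df["start"], df["end"])
        counts = df[design.sample_ids].to_numpy(dtype=np.int64)
        return cls(windows, counts, design, np.asarray(meta["library_sizes"]))


def _windows_from_coords(chroms, starts, ends) -> list[Window]:
    windows = []
    idx = 0
    prev_chrom = None
    for c, s, e in zip(chroms, starts, ends):
        if c != prev_chrom:
            idx = 0
            prev_chrom = c
        windows.append(Window(str(c), int(s), int(e), idx))
        idx += 1
    return windows


class _WindowGrid:
    """Maps a genomic position to its row in the window list.

    Requires the regular tiling produced by ``build_windows``.
    """

    def __init__(self, windows: list[Window]):
        if not windows:
            raise ValueError("no windows")
        self.window_size = max(w.length for w in windows)
        self.offsets: dict[str, int] = {}
        self.lengths: dict[str, int] = {}
        for row, w in enumerate(windows):
            if w.index == 0:
                self.offsets[w.chrom] = row
            self.lengths[w.chrom] = w.end
        # sanity: rows per chromosome must match the tiling
        for chrom, length in self.lengths.items():
            n = -(-length // self.window_size)
            last = self.offsets[chrom] + n - 1
            if windows[last].chrom != chrom or windows[last].end != length:
                raise ValueError("windows do not form a regular tiling")

    def row(self, chrom: str, pos: int) -> int | None:
        off = self.offsets.get(chrom)
        if off is None:
            return None
        pos = min(max(pos, 0), self.lengths[chrom] - 1)
        return off + pos // self.window_size


def iter_bed_fragments(path: str | Path) -> Iterator[tuple[str, int, int]]:
    """Yield (chrom, start, end) fragments from a BED3+ file.

    Intervals are taken as full fragments; no strand extension is applied.
    """
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: fewer than 3 BED columns")
            yield parts[0], int(parts[1]), int(parts[2])


def count_bed_fragments(
    path: str | Path, windows: list[Window], config: PipelineConfig
) -> tuple[np.ndarray, CountingStats]:
    """Count BED intervals (pre-made fragments) into windows by midpoint."""
    grid = _WindowGrid(windows)
    column = np.zeros(len(windows), dtype=np.int64)
    stats = CountingStats()
    last_start: dict[str, int] = {}
    for chrom, start, end in iter_bed_fragments(path):
        if chrom in last_start and start < last_start[chrom]:
            raise ValueError(f"{path}: BED input not coordinate-sorted at {chrom}:{start}")
        last_start[chrom] = start
        row = grid.row(chrom, (start + end) // 2)
        if row is None:
            stats.unresolved_chroms[chrom] = stats.unresolved_chroms.get(chrom, 0) + 1
            continue
        column[row] += 1
        stats.usable += 1
    if stats.usable == 0:
        warnings.warn(f"{path}: no usable fragments; all-zero column", stacklevel=2)
    return column, stats


def count_bam_fragments(
    path: str | Path, windows: list[Window], config: PipelineConfig
) -> tuple[np.ndarray, CountingStats]:
    """Count BAM/SAM alignments into windows by fragment midpoint.

    Properly paired reads use the pair span (counted once, from the leftmost
    mate); other reads are extended to ``config.fragment_length`` from the 5'
    end in the strand direction. Unmapped, secondary, supplementary and
    duplicate-flagged records are skipped. Duplicate flags are honored but
    no deduplication is performed.
    """
    import pysam

    grid = _WindowGrid(windows)
    column = np.zeros(len(windows), dtype=np.int64)
    stats = CountingStats()
    last_start: dict[str, int] = {}
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam:
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate):
                stats.skipped_flagged += 1
                continue
            chrom = read.reference_name
            start = read.reference_start
            if chrom in last_start and start < last_start[chrom]:
                raise ValueError(f"{path}: alignments not coordinate-sorted at {chrom}:{start}")
            last_start[chrom] = start
            if chrom not in grid.offsets:
                stats.unresolved_chroms[chrom] = stats.unresolved_chroms.get(chrom, 0) + 1
                continue
            if read.is_paired and read.is_proper_pair:
                tlen = read.template_length
                if tlen <= 0:
                    continue  # the pair is counted from its leftmost mate
                frag_start, frag_end = start, start + tlen
            elif read.is_reverse:
                frag_end = read.reference_end
                frag_start = frag_end - config.fragment_length
            else:
                frag_start = start
                frag_end = frag_start + config.fragment_length
            row = grid.row(chrom, (frag_start + frag_end) // 2)
            if row is None:
                continue
            column[row] += 1
            stats.usable += 1
    if stats.usable == 0:
        warnings.warn(f"{path}: no usable fragments; all-zero column", stacklevel=2)
    return column, stats


def count_fragments(
    path: str | Path, windows: list[Window], config: PipelineConfig
) -> tuple[np.ndarray, CountingStats]:
    """Dispatch on file suffix: .bed -> BED dialect, else BAM/SAM."""
    if str(path).endswith((".bed", ".bed.txt")):
        return count_bed_fragments(path, windows, config)
    return count_bam_fragments(path, windows, config)


def build_count_matrix(
    design: SampleDesign, windows: list[Window], config: PipelineConfig
) -> tuple[WindowCountMatrix, list[CountingStats]]:
    """Count every sample's alignment file into one matrix."""
    cols, all_stats = [], []
    for sample in design.samples:
        if sample.alignment_path is None:
            raise ValueError(f"sample {sample.sample_id} has no alignment_path")
        col, stats = count_fragments(sample.alignment_path, windows, config)
        cols.append(col)
        all_stats.append(stats)
    counts = np.stack(cols, axis=1)
    return WindowCountMatrix(windows, counts, design, counts.sum(axis=0)), all_stats


def filter_low_total(
    matrix: WindowCountMatrix, min_total_reads: int
) -> tuple[WindowCountMatrix, int]:
    """Remove windows whose count summed across all samples is < threshold.

    Library sizes are carried over unchanged: they reflect total assigned
    fragments, not the post-filter subset.
    """
    if matrix.n_samples < 1:
        raise ValueError("matrix has no samples")
    keep = matrix.counts.sum(axis=1) >= min_total_reads
    filtered = WindowCountMatrix(
        [w for w, k in zip(matrix.windows, keep) if k],
        matrix.counts[keep],
        matrix.design,
        matrix.library_sizes,
    )
    return filtered, int((~keep).sum())
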