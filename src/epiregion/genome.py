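"""Reference genome representation, window tiling and CpG features.

Coordinates are 0-based half-open everywhere inside the package. BED is
written as-is; GFF3/GTF (1-based inclusive) is converted on ingest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np


@dataclass(frozen=True, slots=True)
class Window:
    """One tile of the genomic grid: ``[start, end)`` on ``chrom``.

    ``index`` is the ordinal of the window within its chromosome.
    """

    chrom: str
    start: int
    end: int
    index: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty window {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeIndex:
    """Ordered chromosomes with lengths plus a sequence accessor.

    Sequences are returned uppercased; only A, C, G, T and N are expected.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("no chromosomes")
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}
        self.chromosomes: list[tuple[str, int]] = [
            (name, len(seq)) for name, seq in self._seqs.items()
        ]
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has length {length}")
        self._lengths = dict(self.chromosomes)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        """Load a genome from FASTA (indexed with pyfaidx)."""
        from pyfaidx import Fasta

        fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    # -- accessors ---------------------------------------------------------

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the uppercase sequence of ``chrom:[start, end)``."""
        length = self.chrom_length(chrom)
        if start < 0 or end > length or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds [0, {length})"
            )
        return self._seqs[chrom][start:end]

    def to_fasta(self, path: str | Path, line_width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, _ in self.chromosomes:
                fh.write(f">{name}\n")
                seq = self._seqs[name]
                for i in range(0, len(seq), line_width):
                    fh.write(seq[i : i + line_width] + "\n")


def build_windows(genome: GenomeIndex, window_size: int) -> list[Window]:
    """Tile every chromosome left to right into ``window_size`` windows.

    The final window of a chromosome may be shorter than ``window_size``;
    partial trailing windows are kept. The summed window span equals the
    total genome length.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not genome.chromosomes:
        raise ValueError("no chromosomes")
    windows: list[Window] = []
    for chrom, length in genome.chromosomes:
        for i, start in enumerate(range(0, length, window_size)):
            windows.append(Window(chrom, start, min(start + window_size, length), i))
    return windows


def cpg_features(genome: GenomeIndex, chrom: str, start: int, end: int) -> tuple[int, float]:
    """Count CG dinucleotides fully inside ``[start, end)`` and their density.

    A CpG at position ``i`` requires ``seq[i:i+2] == "CG"`` with ``i+2 <= end``,
    so dinucleotides spanning the right boundary are excluded. Density is
    expressed per 100 bp. CpG is its own reverse complement, so the count is
    strand-symmetric by construction; N never matches.
    """
    seq = genome.fetch(chrom, start, end)
    # "CG" occurrences cannot overlap each other, so str.count is exact
    count = seq.count("CG")
    density = 100.0 * count / (end - start)
    return count, density


def windows_to_bed(windows: Iterable[Window], path: str | Path) -> None:
    """Write windows as BED3."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\n")


def window_grid_arrays(windows: list[Window]) -> dict[str, np.ndarray]:
    """Column arrays (chrom, start, end) for vectorized interval work."""
    return {
        "chrom": np.array([w.chrom for w in windows], dtype=object),
        "start": np.array([w.start for w in windows], dtype=np.int64),
        "end": np.array([w.end for w in windows], dtype=np.int64),
    }
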