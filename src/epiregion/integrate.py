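"""Cross-set analyses: overlaps, gene association, co-localization,
cluster scan, histone-retention fraction, sncRNA tallies and sample PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counts import WindowCountMatrix
from .genome import GenomeIndex
from .regions import RegionSet

Interval = tuple[str, int, int]

NCRNA_CLASSES = ("miRNA", "piRNA", "stRNA", "lncRNA", "rRNA", "mitoRNA", "other")


# ---------------------------------------------------------------------------
# ncRNA tables

def load_ncrna_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-ncRNA TSV: name, class, chrom, start, end, p_value.

    Rows with unknown location (empty / NA chrom) are kept but excluded from
    interval operations. Unknown classes are mapped to "other".
    """
    df = pd.read_csv(path, sep="\t")
    required = {"name", "class", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing ncRNA table columns {sorted(missing)}")
    df["name"] = df["name"].astype(str).str.strip()
    if (df["name"] == "").any():
        raise ValueError(f"{path}: empty ncRNA names")
    bad_p = ~df["p_value"].between(0, 1)
    if bad_p.any():
        raise ValueError(f"{path}: p_value outside [0, 1] in {int(bad_p.sum())} rows")
    df["class"] = df["class"].where(df["class"].isin(NCRNA_CLASSES), "other")
    return df


def tally_sncrna_classes(table: pd.DataFrame, p_threshold: float = 1e-4) -> dict[str, int]:
    """Count differential sncRNA per class at p < threshold."""
    cls = table.loc[table["p_value"] < p_threshold, "class"]
    cls = cls.where(cls.isin(NCRNA_CLASSES), "other")
    counts = cls.value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in NCRNA_CLASSES}


# ---------------------------------------------------------------------------
# Venn overlaps

@dataclass
class OverlapReport:
    """Venn-style overlap summary for 2-3 named sets.

    ``cells`` maps each non-empty combination of set names (frozenset) to,
    per member set, the number of that set's elements whose full overlap
    pattern equals the combination; every element is counted in exactly one
    cell. ``members`` lists the element identifiers per cell and set.
    """

    set_sizes: dict[str, int]
    cells: dict[frozenset, dict[str, int]]
    members: dict[frozenset, dict[str, list[str]]]
    mode: str  # "interval" | "name"

    def pairwise_intersection(self, a: str, b: str) -> dict[str, int]:
        """|A∩B| from both perspectives: elements of each set overlapping
        at least one element of the other."""
        out = {}
        for ref in (a, b):
            other = b if ref == a else a
            out[ref] = sum(
                counts.get(ref, 0)
                for cell, counts in self.cells.items()
                if ref in cell and other in cell
            )
        return out

    def validate(self) -> None:
        """Inclusion-exclusion consistency per set pair, per perspective."""
        names = list(self.set_sizes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                inter = self.pairwise_intersection(a, b)
                union = self.set_sizes[a] + self.set_sizes[b] - inter[a]
                alt = self.set_sizes[a] + self.set_sizes[b] - inter[b]
                # union computed from either perspective must match the
                # count of elements outside the intersection plus it
                only_a = self.set_sizes[a] - inter[a]
                only_b = self.set_sizes[b] - inter[b]
                assert union == only_a + self.set_sizes[b]
                assert alt == only_b + self.set_sizes[a]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell in sorted(self.cells, key=lambda c: (len(c), sorted(c))):
            for set_name, count in sorted(self.cells[cell].items()):
                rows.append(
                    {
                        "cell": "&".join(sorted(cell)),
                        "set": set_name,
                        "count": count,
                        "members": ";".join(self.members[cell][set_name]),
                    }
                )
        return pd.DataFrame(rows, columns=["cell", "set", "count", "members"])


def _overlaps_any(interval: Interval, others: Sequence[Interval]) -> bool:
    chrom, start, end = interval
    return any(c == chrom and start < e and end > s for c, s, e in others)


def interval_overlap_sets(sets: Mapping[str, RegionSet | Sequence[Interval]]) -> OverlapReport:
    """Venn overlap of 2-3 region sets; overlap = >=1 shared bp, same chrom.

    Each region is counted once, in the cell of its full overlap pattern
    (a region overlapping partners in both other sets belongs to the triple
    cell). Because many-to-one overlaps exist, each cell reports a count per
    member set.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("interval_overlap_sets takes 2-3 sets")
    named: dict[str, list[tuple[Interval, str]]] = {}
    for name, rs in sets.items():
        if isinstance(rs, RegionSet):
            named[name] = [((r.chrom, r.start, r.end), r.region_id) for r in rs]
        else:
            named[name] = [((c, s, e), f"{name}:{c}:{s}-{e}") for c, s, e in rs]

    cells: dict[frozenset, dict[str, int]] = {}
    members: dict[frozenset, dict[str, list[str]]] = {}
    for name, items in named.items():
        for interval, ident in items:
            pattern = frozenset(
                [name]
                + [
                    other
                    for other in named
                    if other != name
                    and _overlaps_any(interval, [iv for iv, _ in named[other]])
                ]
            )
            cells.setdefault(pattern, {}).setdefault(name, 0)
            cells[pattern][name] += 1
            members.setdefault(pattern, {}).setdefault(name, []).append(ident)
    report = OverlapReport(
        {name: len(items) for name, items in named.items()}, cells, members, "interval"
    )
    report.validate()
    return report


def name_overlap(tables: Mapping[str, pd.DataFrame | Iterable[str]]) -> OverlapReport:
    """Venn on ncRNA name sets (exact string match after whitespace trim).

    Duplicate names within one table are deduplicated with a warning count
    folded into the report's set sizes.
    """
    import warnings

    if not 2 <= len(tables) <= 3:
        raise ValueError("name_overlap takes 2-3 tables")
    name_sets: dict[str, set[str]] = {}
    for set_name, table in tables.items():
        if isinstance(table, pd.DataFrame):
            names = [str(n).strip() for n in table["name"]]
        else:
            names = [str(n).strip() for n in table]
        dupes = len(names) - len(set(names))
        if dupes:
            warnings.warn(f"{set_name}: {dupes} duplicate names deduplicated", stacklevel=2)
        name_sets[set_name] = set(names)

    cells: dict[frozenset, dict[str, int]] = {}
    members: dict[frozenset, dict[str, list[str]]] = {}
    for set_name, names in name_sets.items():
        for n in sorted(names):
            pattern = frozenset(s for s, other in name_sets.items() if n in other)
            cells.setdefault(pattern, {}).setdefault(set_name, 0)
            cells[pattern][set_name] += 1
            members.setdefault(pattern, {}).setdefault(set_name, []).append(n)
    report = OverlapReport({k: len(v) for k, v in name_sets.items()}, cells, members, "name")
    report.validate()
    return report


# ---------------------------------------------------------------------------
# Gene annotation and association

@dataclass(frozen=True)
class Gene:
    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 0-based half-open after ingest
    end: int
    strand: str = "."


def _parse_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if "=" in attr:  # GFF3: key=value;key=value
        for part in attr.strip().split(";"):
            if "=" in part:
                k, v = part.split("=", 1)
                out[k.strip()] = v.strip()
    else:  # GTF: key "value"; key "value";
        for part in attr.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            bits = part.split(None, 1)
            if len(bits) == 2:
                out[bits[0]] = bits[1].strip().strip('"')
    return out


def load_gene_annotation(path: str | Path) -> tuple[list[Gene], int]:
    """Parse gene-level features from GFF3/GTF into 0-based half-open spans.

    Returns (genes, n_malformed_rows_skipped). Only rows with feature type
    "gene" are used; GFF3 ``ID``/``Name`` and GTF ``gene_id``/``gene_name``
    attribute dialects are both recognized.
    """
    genes: list[Gene] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                skipped += 1
                continue
            if parts[2] != "gene":
                continue
            try:
                start = int(parts[3]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(parts[4])
            except ValueError:
                skipped += 1
                continue
            if start < 0 or end <= start:
                skipped += 1
                continue
            attrs = _parse_attributes(parts[8])
            gid = attrs.get("ID") or attrs.get("gene_id") or f"gene:{parts[0]}:{start}"
            gname = attrs.get("Name") or attrs.get("gene_name") or gid
            genes.append(Gene(gid, gname, parts[0], start, end, parts[6]))
    return genes, skipped


@dataclass(frozen=True)
class GeneAssociation:
    region_id: str
    gene_id: str
    gene_name: str
    distance: int  # bp, 0 if overlapping
    category: str | None = None


def _edge_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge bp distance of two half-open intervals; 0 if they
    overlap or are adjacent."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(b_start - a_end, a_start - b_end, 0)


def associate_genes(
    region_set: RegionSet,
    genes: Sequence[Gene],
    gene_proximity: int = 10_000,
    categories: Mapping[str, str] | None = None,
) -> tuple[list[GeneAssociation], list[str]]:
    """Associate regions with genes within ``gene_proximity`` bp.

    Distance is edge-to-edge on spans only (strand-symmetric); a region may
    associate with several genes and vice versa. Returns the association
    list and the region_ids left intergenic.
    """
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    associations: list[GeneAssociation] = []
    intergenic: list[str] = []
    for r in region_set:
        found = False
        for g in by_chrom.get(r.chrom, ()):
            d = _edge_distance(r.start, r.end, g.start, g.end)
            if d <= gene_proximity:
                associations.append(
                    GeneAssociation(
                        r.region_id, g.gene_id, g.gene_name, d,
                        categories.get(g.gene_name) if categories else None,
                    )
                )
                found = True
        if not found:
            intergenic.append(r.region_id)
    return associations, intergenic


def associations_to_frame(associations: Sequence[GeneAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": a.region_id,
                "gene_id": a.gene_id,
                "gene_name": a.gene_name,
                "distance": a.distance,
                "category": a.category,
            }
            for a in associations
        ],
        columns=["region_id", "gene_id", "gene_name", "distance", "category"],
    )


def tally_gene_categories(associations: Sequence[GeneAssociation]) -> dict[str, int]:
    """Generic category tally over associated genes (deduplicated by gene)."""
    seen: dict[str, str] = {}
    for a in associations:
        if a.category is not None:
            seen[a.gene_name] = a.category
    counts: dict[str, int] = {}
    for cat in seen.values():
        counts[cat] = counts.get(cat, 0) + 1
    return dict(sorted(counts.items()))


# ---------------------------------------------------------------------------
# Co-localization

@dataclass
class ColocSite:
    chrom: str
    start: int
    end: int
    members: dict[str, list[str]]  # set name -> feature identifiers

    @property
    def n_sets(self) -> int:
        return len(self.members)


def colocalize(
    feature_sets: Mapping[str, Sequence[tuple[str, int, int, str]]],
    coloc_window: int = 100_000,
) -> list[ColocSite]:
    """Multi-mark co-localization sites within a genomic span.

    Input: per set name, located features as (chrom, start, end, id);
    unknown-location features must be excluded by the caller. Feature
    midpoints on the same chromosome are clustered by single linkage at
    ``coloc_window``; clusters drawing features from >= 2 distinct sets are
    reported, spanning the min start to max end of member features.
    """
    feats: list[tuple[str, int, int, int, str, str]] = []  # chrom, mid, start, end, set, id
    for set_name, features in feature_sets.items():
        for chrom, start, end, ident in features:
            feats.append((chrom, (start + end) // 2, start, end, set_name, ident))
    feats.sort(key=lambda f: (f[0], f[1]))

    sites: list[ColocSite] = []
    cluster: list[tuple[str, int, int, int, str, str]] = []

    def flush() -> None:
        if not cluster:
            return
        sets_present = {f[4] for f in cluster}
        if len(sets_present) >= 2:
            members: dict[str, list[str]] = {}
            for f in cluster:
                members.setdefault(f[4], []).append(f[5])
            sites.append(
                ColocSite(
                    cluster[0][0],
                    min(f[2] for f in cluster),
                    max(f[3] for f in cluster),
                    members,
                )
            )

    for f in feats:
        if cluster and (f[0] != cluster[-1][0] or f[1] - cluster[-1][1] > coloc_window):
            flush()
            cluster = []
        cluster.append(f)
    flush()
    return sites


def coloc_to_frame(sites: Sequence[ColocSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_sets": s.n_sets,
                "members": ";".join(
                    f"{name}={','.join(ids)}" for name, ids in sorted(s.members.items())
                ),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sets", "members"])


# ---------------------------------------------------------------------------
# Chromosomal cluster scan

@dataclass
class ClusterCall:
    chrom: str
    start: int
    end: int
    n_regions: int
    p_value: float  # Poisson upper tail under the genome-wide rate


def scan_clusters(
    region_set: RegionSet,
    genome: GenomeIndex,
    scan_window: int = 2_000_000,
    step: int = 100_000,
    alpha: float = 0.05,
) -> tuple[list[ClusterCall], list[str]]:
    """Sliding-window Poisson scan for over-represented region clusters.

    Windows of ``scan_window`` bp advance by ``step``; a window is flagged
    when the Poisson upper-tail probability of its region count (midpoint
    membership) under the genome-wide rate is below ``alpha``. Overlapping
    flagged windows merge into one cluster call. Chromosomes shorter than
    the scan window are skipped and reported.
    """
    if len(region_set) < 1:
        raise ValueError("need at least one region")
    rate = len(region_set) / genome.total_length  # regions per bp
    lam = rate * scan_window
    mids: dict[str, np.ndarray] = {}
    for r in region_set:
        mids.setdefault(r.chrom, [])
    for r in region_set:
        mids[r.chrom].append(r.midpoint)  # type: ignore[union-attr]
    mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}

    skipped: list[str] = []
    calls: list[ClusterCall] = []
    for chrom, length in genome.chromosomes:
        if scan_window > length:
            skipped.append(chrom)
            continue
        m = mids.get(chrom)
        if m is None or len(m) == 0:
            continue
        flagged: list[tuple[int, int]] = []
        for start in range(0, length - scan_window + 1, step):
            end = start + scan_window
            k = int(np.searchsorted(m, end) - np.searchsorted(m, start))
            if k > 0 and sps.poisson.sf(k - 1, lam) < alpha:
                flagged.append((start, end))
        # merge overlapping flagged windows
        for start, end in flagged:
            if calls and calls[-1].chrom == chrom and start <= calls[-1].end:
                calls[-1].end = max(calls[-1].end, end)
            else:
                calls.append(ClusterCall(chrom, start, end, 0, 1.0))
        # fill counts and p for merged spans on this chromosome
        for call in calls:
            if call.chrom == chrom:
                k = int(np.searchsorted(m, call.end) - np.searchsorted(m, call.start))
                call.n_regions = k
                span_lam = rate * (call.end - call.start)
                call.p_value = float(sps.poisson.sf(k - 1, span_lam))
    return calls, skipped


# ---------------------------------------------------------------------------
# Histone retention fraction

@dataclass(frozen=True)
class RetentionStats:
    total_retained_bp: int
    genome_bp: int
    percent: float
    n_intervals_merged: int


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of half-open intervals, sorted and merged."""
    ivs = sorted(intervals)
    merged: list[list] = []
    for chrom, start, end in ivs:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [(c, s, e) for c, s, e in merged]


def retention_fraction(
    intervals: Iterable[Interval], genome: GenomeIndex
) -> RetentionStats:
    """Fraction of the genome covered by the union of retained-histone
    intervals, as a percentage.

    The interval source is the caller's choice (called DHRs, a
    coverage-threshold track, peak calls); the statistic is agnostic.
    """
    merged = merge_intervals(intervals)
    for chrom, start, end in merged:
        length = genome.chrom_length(chrom)
        if start < 0 or end > length:
            raise ValueError(f"interval {chrom}:{start}-{end} outside genome bounds")
    total = sum(e - s for _, s, e in merged)
    genome_bp = genome.total_length
    return RetentionStats(total, genome_bp, 100.0 * total / genome_bp, len(merged))


# ---------------------------------------------------------------------------
# Sample PCA

def pca_samples(matrix: WindowCountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """First two principal-component coordinates of the samples.

    Counts are transformed to log2(CPM + 1), windows (rows) are centered
    and the SVD taken; sample coordinates are the unit right-singular
    vectors, so they are invariant to duplicating windows, with the
    variance-explained ratios reported alongside. Component sign is fixed
    by making each coordinate vector's largest-magnitude entry positive.
    """
    if matrix.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    sizes = np.asarray(matrix.library_sizes, dtype=float)
    sizes = np.where(sizes > 0, sizes, 1.0)
    cpm = matrix.counts / sizes * 1e6
    x = np.log2(cpm + 1.0)
    x = x - x.mean(axis=1, keepdims=True)  # center windows
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = float((s ** 2).sum())
    n_comp = min(2, vt.shape[0])
    coords = vt[:n_comp].T.copy()  # (n_samples, n_comp), unit columns
    for j in range(coords.shape[1]):
        k = int(np.abs(coords[:, j]).argmax())
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    if total_var <= 0:
        return np.zeros((matrix.n_samples, n_comp)), np.zeros(n_comp)
    var_explained = (s[:n_comp] ** 2) / total_var
    return coords, var_explained
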