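import numpy as np
import pandas as pd
import pytest

from epiregion import (
    GenomeIndex,
    WindowCountMatrix,
    associate_genes,
    colocalize,
    interval_overlap_sets,
    merge_intervals,
    name_overlap,
    pca_samples,
    retention_fraction,
    scan_clusters,
    tally_sncrna_classes,
)
from epiregion.integrate import Gene, load_gene_annotation, load_ncrna_table
from epiregion.regions import EpiRegion, RegionSet


def region_set(intervals, mark="DMR"):
    return RegionSet(
        [
            EpiRegion(c, s, e, 1, 1, 1e-8, 0.0, region_id=f"{mark}:{c}:{s}-{e}")
            for c, s, e in intervals
        ],
        mark=mark,
    )


class TestIntervalOverlap:
    def test_single_overlap(self):
        rep = interval_overlap_sets({"A": [("chr1", 0, 100)], "B": [("chr1", 50, 150)]})
        assert rep.pairwise_intersection("A", "B") == {"A": 1, "B": 1}

    def test_disjoint_sets(self):
        rep = interval_overlap_sets(
            {"A": [("chr1", 0, 100)], "B": [("chr1", 200, 300), ("chr2", 0, 50)]}
        )
        assert rep.pairwise_intersection("A", "B") == {"A": 0, "B": 0}
        assert rep.set_sizes == {"A": 1, "B": 2}

    def test_triple_cell_membership(self):
        rep = interval_overlap_sets(
            {
                "A": [("chr1", 0, 100)],
                "B": [("chr1", 50, 150)],
                "C": [("chr1", 90, 120), ("chr2", 0, 10)],
            }
        )
        triple = frozenset({"A", "B", "C"})
        assert rep.cells[triple] == {"A": 1, "B": 1, "C": 1}

    def test_random_sets_match_all_pairs_oracle(self):
        """Venn cells equal a brute-force O(n^2) all-pairs overlap scan."""
        rng = np.random.default_rng(8)

        def random_set():
            out = []
            for _ in range(200):
                chrom = f"chr{rng.integers(1, 4)}"
                start = int(rng.integers(0, 100_000))
                out.append((chrom, start, start + int(rng.integers(50, 2000))))
            return out

        sets = {name: random_set() for name in "ABC"}
        rep = interval_overlap_sets(sets)
        for name, items in sets.items():
            for iv in items:
                pattern = frozenset(
                    [name]
                    + [
                        o
                        for o in sets
                        if o != name
                        and any(
                            iv[0] == c and iv[1] < e and iv[2] > s
                            for c, s, e in sets[o]
                        )
                    ]
                )
                assert rep.cells[pattern][name] >= 1
        # totals per set across cells equal set sizes
        for name, size in rep.set_sizes.items():
            total = sum(c.get(name, 0) for c in rep.cells.values())
            assert total == size

    def test_region_set_input(self):
        rs1 = region_set([("chr1", 0, 100), ("chr1", 500, 600)], "F1")
        rs2 = region_set([("chr1", 90, 110)], "F2")
        rep = interval_overlap_sets({"F1": rs1, "F2": rs2})
        assert rep.pairwise_intersection("F1", "F2") == {"F1": 1, "F2": 1}

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(ValueError, match="2-3"):
            interval_overlap_sets({"A": [("chr1", 0, 1)]})


class TestNameOverlap:
    def test_pairwise(self):
        rep = name_overlap({"X": ["a", "b", "c"], "Y": ["b", "c", "d"]})
        assert rep.pairwise_intersection("X", "Y") == {"X": 2, "Y": 2}

    def test_identical_tables(self):
        rep = name_overlap({"X": ["a", "b"], "Y": ["a", "b"]})
        assert rep.pairwise_intersection("X", "Y") == {"X": 2, "Y": 2}

    def test_three_sets_one_shared(self):
        rep = name_overlap({"X": ["a", "q"], "Y": ["a", "r"], "Z": ["a", "s"]})
        assert rep.cells[frozenset("XYZ")] == {"X": 1, "Y": 1, "Z": 1}

    def test_duplicates_warn_and_dedupe(self):
        with pytest.warns(UserWarning, match="duplicate"):
            rep = name_overlap({"X": ["a", "a", "b"], "Y": ["b"]})
        assert rep.set_sizes["X"] == 2

    def test_whitespace_trimmed_case_preserved(self):
        rep = name_overlap({"X": [" miR-21 "], "Y": ["miR-21"], "Z": ["MIR-21"]})
        assert rep.pairwise_intersection("X", "Y") == {"X": 1, "Y": 1}
        assert rep.pairwise_intersection("X", "Z") == {"X": 0, "Z": 0}


class TestGeneAssociation:
    GENES = [Gene("g1", "Gene1", "chr1", 10_000, 20_000)]

    def test_within_proximity(self):
        rs = region_set([("chr1", 5000, 6000)])
        assoc, intergenic = associate_genes(rs, self.GENES, 10_000)
        assert len(assoc) == 1 and assoc[0].distance == 4000
        assert intergenic == []

    def test_beyond_proximity_intergenic(self):
        rs = region_set([("chr1", 36_001, 37_000)])  # 16,001 bp past gene end
        assoc, intergenic = associate_genes(rs, self.GENES, 10_000)
        assert assoc == [] and len(intergenic) == 1

    def test_overlap_distance_zero(self):
        rs = region_set([("chr1", 12_000, 13_000)])
        assoc, _ = associate_genes(rs, self.GENES, 10_000)
        assert assoc[0].distance == 0

    def test_many_to_many(self):
        genes = self.GENES + [Gene("g2", "Gene2", "chr1", 22_000, 30_000)]
        rs = region_set([("chr1", 20_500, 21_000)])
        assoc, _ = associate_genes(rs, genes, 10_000)
        assert {a.gene_id for a in assoc} == {"g1", "g2"}

    def test_strand_symmetry(self):
        plus = [Gene("g", "G", "chr1", 10_000, 20_000, "+")]
        minus = [Gene("g", "G", "chr1", 10_000, 20_000, "-")]
        rs = region_set([("chr1", 0, 5000)])
        a_plus, _ = associate_genes(rs, plus, 10_000)
        a_minus, _ = associate_genes(rs, minus, 10_000)
        assert [a.distance for a in a_plus] == [a.distance for a in a_minus]

    def test_gff3_and_gtf_dialects(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1;Name=Alpha\n"
            "chr1\tsrc\texon\t1001\t1500\t.\t+\t.\tID=e1\n"
            "badline\n"
        )
        genes, skipped = load_gene_annotation(gff)
        assert len(genes) == 1 and skipped == 1
        assert (genes[0].start, genes[0].end, genes[0].gene_name) == (1000, 2000, "Alpha")
        gtf = tmp_path / "g.gtf"
        gtf.write_text('chr1\tsrc\tgene\t501\t900\t.\t-\t.\tgene_id "g2"; gene_name "Beta";\n')
        genes, _ = load_gene_annotation(gtf)
        assert (genes[0].start, genes[0].end, genes[0].gene_name) == (500, 900, "Beta")


class TestColocalize:
    def test_three_marks_one_site(self):
        sites = colocalize(
            {
                "DMR": [("chr1", 9_000, 11_000, "d1")],
                "ncRNA": [("chr1", 59_000, 61_000, "n1")],
                "DHR": [("chr1", 89_000, 91_000, "h1")],
            },
            coloc_window=100_000,
        )
        assert len(sites) == 1
        assert set(sites[0].members) == {"DMR", "ncRNA", "DHR"}

    def test_single_set_never_a_site(self):
        sites = colocalize(
            {"DMR": [("chr1", 0, 100, "a"), ("chr1", 5000, 5100, "b")],
             "DHR": []},
            coloc_window=100_000,
        )
        assert sites == []

    def test_different_chromosomes_never_colocalize(self):
        sites = colocalize(
            {"DMR": [("chr1", 0, 100, "a")], "DHR": [("chr2", 0, 100, "b")]},
            coloc_window=100_000,
        )
        assert sites == []

    def test_gap_splits_clusters(self):
        sites = colocalize(
            {
                "DMR": [("chr1", 0, 100, "a"), ("chr1", 500_000, 500_100, "c")],
                "DHR": [("chr1", 1_000, 1_100, "b"), ("chr1", 501_000, 501_100, "d")],
            },
            coloc_window=100_000,
        )
        assert len(sites) == 2
        assert all(s.n_sets == 2 for s in sites)


class TestScanClusters:
    def test_packed_regions_form_one_cluster(self):
        genome = GenomeIndex({"chr1": "A" * 1_000_000})
        # emulate a 100-Mb genome density by padding chromosome list
        big = GenomeIndex({"chr1": "A" * 1_000_000})
        rs = region_set([("chr1", 10_000 + i * 5_000, 10_500 + i * 5_000) for i in range(10)])
        calls, _ = scan_clusters(rs, big, scan_window=100_000, step=10_000, alpha=0.05)
        merged_with_all = [c for c in calls if c.n_regions == 10]
        assert len(merged_with_all) >= 1

    def test_single_region_no_cluster(self):
        genome = GenomeIndex({"chr1": "A" * 1_000_000})
        rs = region_set([("chr1", 0, 1000)])
        calls, _ = scan_clusters(rs, genome, scan_window=100_000, step=50_000)
        assert calls == []

    def test_short_chromosome_skipped(self):
        genome = GenomeIndex({"chr1": "A" * 1_000_000, "chrM": "A" * 10_000})
        rs = region_set([("chr1", 0, 1000)])
        _, skipped = scan_clusters(rs, genome, scan_window=100_000, step=50_000)
        assert skipped == ["chrM"]

    def test_uniform_scatter_calibrated(self):
        """Under uniform placement roughly an alpha fraction of scan windows
        is flagged before merging (here: few or no clusters survive)."""
        rng = np.random.default_rng(2)
        genome = GenomeIndex({"chr1": "A" * 1_000_000})
        starts = np.sort(rng.integers(0, 999_000, size=50))
        rs = region_set([("chr1", int(s), int(s) + 500) for s in starts])
        calls, _ = scan_clusters(rs, genome, scan_window=100_000, step=10_000, alpha=0.01)
        flagged_bp = sum(c.end - c.start for c in calls)
        assert flagged_bp <= 0.2 * 1_000_000


class TestRetention:
    def test_disjoint_fraction(self):
        genome = GenomeIndex({"chr1": "A" * 1000})
        stats = retention_fraction([("chr1", 0, 100), ("chr1", 200, 300)], genome)
        assert stats.percent == pytest.approx(20.0)

    def test_overlap_union_semantics(self):
        genome = GenomeIndex({"chr1": "A" * 1000})
        stats = retention_fraction([("chr1", 0, 100), ("chr1", 50, 150)], genome)
        assert stats.percent == pytest.approx(15.0)
        assert stats.total_retained_bp == 150

    def test_empty_set(self):
        genome = GenomeIndex({"chr1": "A" * 1000})
        assert retention_fraction([], genome).percent == 0.0

    def test_invariant_to_fragmentation(self):
        genome = GenomeIndex({"chr1": "A" * 10_000})
        whole = [("chr1", 100, 900)]
        pieces = [("chr1", 500, 900), ("chr1", 100, 400), ("chr1", 350, 600)]
        assert retention_fraction(whole, genome).percent == \
            retention_fraction(pieces, genome).percent

    def test_out_of_bounds_rejected(self):
        genome = GenomeIndex({"chr1": "A" * 1000})
        with pytest.raises(ValueError, match="bounds"):
            retention_fraction([("chr1", 900, 1100)], genome)

    def test_merge_intervals(self):
        assert merge_intervals(
            [("chr1", 5, 10), ("chr1", 0, 6), ("chr2", 0, 3)]
        ) == [("chr1", 0, 10), ("chr2", 0, 3)]


class TestSncrnaTally:
    def test_threshold_filters_classes(self):
        table = pd.DataFrame(
            {
                "name": ["p1", "p2", "p3", "m1"],
                "class": ["piRNA", "piRNA", "piRNA", "miRNA"],
                "p_value": [1e-5, 1e-5, 1e-5, 0.01],
            }
        )
        tallies = tally_sncrna_classes(table, 1e-4)
        assert tallies["piRNA"] == 3 and tallies["miRNA"] == 0

    def test_empty_table_all_zero(self):
        table = pd.DataFrame({"name": [], "class": [], "p_value": []})
        assert set(tally_sncrna_classes(table).values()) == {0}

    def test_unknown_class_maps_to_other(self):
        table = pd.DataFrame(
            {"name": ["x"], "class": ["snoRNA"], "p_value": [1e-6]}
        )
        assert tally_sncrna_classes(table)["other"] == 1

    def test_random_table_matches_filter_count(self):
        rng = np.random.default_rng(14)
        classes = rng.choice(["miRNA", "piRNA", "stRNA", "other"], size=500)
        p = rng.random(500) * 1e-3
        table = pd.DataFrame({"name": [f"n{i}" for i in range(500)],
                              "class": classes, "p_value": p})
        tallies = tally_sncrna_classes(table, 1e-4)
        for cls in ("miRNA", "piRNA", "stRNA", "other"):
            assert tallies[cls] == int(((classes == cls) & (p < 1e-4)).sum())

    def test_loader_validates(self, tmp_path):
        path = tmp_path / "nc.tsv"
        pd.DataFrame(
            {"name": ["a"], "class": ["piRNA"], "chrom": ["chr1"],
             "start": [0], "end": [100], "p_value": [2.0]}
        ).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="p_value"):
            load_ncrna_table(path)


class TestPcaSamples:
    def test_identical_samples_identical_coords(self, matrix_factory):
        m = matrix_factory(np.tile([[5], [9], [2]], (1, 4)))
        coords, _ = pca_samples(m)
        assert np.allclose(coords - coords[0], 0)

    @staticmethod
    def group_structured_counts(seed=23):
        """Two groups that differ in profile (not just depth): half the
        windows are elevated in the exposed pools."""
        rng = np.random.default_rng(seed)
        counts = rng.poisson(20, size=(500, 6))
        counts[:250, 3:] += rng.poisson(60, size=(250, 3))
        return counts

    def test_separated_groups_split_on_pc1(self, matrix_factory):
        m = matrix_factory(self.group_structured_counts())
        coords, var = pca_samples(m)
        pc1 = coords[:, 0]
        assert max(pc1[:3]) < min(pc1[3:]) or min(pc1[:3]) > max(pc1[3:])
        assert var[0] > var[1] >= 0

    def test_row_duplication_leaves_coords_unchanged(self, matrix_factory):
        counts = self.group_structured_counts(seed=29)
        m = matrix_factory(counts)
        m2 = matrix_factory(np.vstack([counts, counts]))
        # same library-size proportions: duplication doubles sizes uniformly
        c1, v1 = pca_samples(m)
        c2, v2 = pca_samples(m2)
        # identical up to LAPACK accumulation noise on the small Gram problem
        assert np.allclose(np.abs(c1), np.abs(c2), atol=1e-4)
        assert np.allclose(v1, v2, atol=1e-4)

    def test_mismatched_matrix_rejected(self, matrix_factory):
        m = matrix_factory(np.ones((10, 4), dtype=int))
        with pytest.raises(ValueError, match="shape"):
            WindowCountMatrix(m.windows, m.counts[:, :1].copy(),
                              m.design, m.library_sizes[:1])
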