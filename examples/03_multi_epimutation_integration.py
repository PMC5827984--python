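"""Integrate region calls with ncRNA tables and gene annotation.

Simulates two generations' worth of region sets plus a differential-ncRNA
table and a toy gene annotation, then runs the cross-set analyses: interval
Venn overlap, name-based ncRNA overlap, 10-kb gene association, 100-kb
multi-mark co-localization, genome retention fraction and sncRNA class
tallies.
"""

from epiregion import (
    PipelineConfig,
    SimulationSpec,
    build_windows,
    call_regions,
    colocalize,
    default_planted_regions,
    interval_overlap_sets,
    name_overlap,
    nb_exact_test,
    retention_fraction,
    simulate_counts,
    simulate_gene_annotation,
    simulate_genome,
    simulate_ncrna_table,
    tally_sncrna_classes,
)
from epiregion.integrate import Gene, associate_genes

config = PipelineConfig(rng_seed=0)
spec = SimulationSpec(n_chromosomes=2, chrom_length=500_000, rng_seed=0)
genome = simulate_genome(spec)
windows = build_windows(genome, spec.window_size)


def one_generation(seed, label):
    s = SimulationSpec(n_chromosomes=2, chrom_length=500_000, rng_seed=seed)
    s.planted_regions = default_planted_regions(s, n_regions=15, n_windows=3,
                                                fold_change=5.0)
    matrix, _ = simulate_counts(s, windows)
    return call_regions(nb_exact_test(matrix), config, mark="DMR", generation=label)


f1 = one_generation(0, "F1")
f3 = one_generation(42, "F3")

venn = interval_overlap_sets({"F1": f1, "F3": f3})
inter = venn.pairwise_intersection("F1", "F3")
print(f"DMR sets: F1 n={len(f1)}, F3 n={len(f3)}; "
      f"interval overlap {inter['F1']} (F1 view) / {inter['F3']} (F3 view)")
# distinct seeds plant regions at different places, so overlap is sparse

ncrna_f1 = simulate_ncrna_table(genome, n_rows=300, generation="F1", seed=1)
ncrna_f3 = simulate_ncrna_table(genome, n_rows=300, generation="F3", seed=2)
shared = name_overlap({"F1": ncrna_f1, "F3": ncrna_f3}).pairwise_intersection("F1", "F3")
print(f"ncRNA name overlap between generations: {shared['F1']} "
      "(names are generation-tagged, so none are shared)")
print(f"differential sncRNA per class at p<1e-4 (F1): "
      f"{ {k: v for k, v in tally_sncrna_classes(ncrna_f1).items() if v} }")

genes_df = simulate_gene_annotation(genome, n_genes=30, seed=3)
genes = [Gene(r.gene_id, r.gene_name, r.chrom, r.start, r.end, r.strand)
         for r in genes_df.itertuples()]
assoc, intergenic = associate_genes(f3, genes, config.gene_proximity)
print(f"F3 regions with a gene within 10 kb: {len(f3) - len(intergenic)}/{len(f3)} "
      f"({len(assoc)} associations)")

located = ncrna_f3[(ncrna_f3["chrom"] != "") & (ncrna_f3["p_value"] < 1e-4)]
sites = colocalize(
    {
        "DMR": [(r.chrom, r.start, r.end, r.region_id) for r in f3],
        "ncRNA": [(r.chrom, int(r.start), int(r.end), r.name)
                  for r in located.itertuples()],
    },
    config.coloc_window,
)
print(f"100-kb co-localization sites with >=2 epimutation types: {len(sites)}")

retention = retention_fraction(f3.intervals(), genome)
print(f"fraction of genome covered by F3 regions: {retention.percent:.3f}% "
      f"({retention.total_retained_bp} of {retention.genome_bp} bp)")
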