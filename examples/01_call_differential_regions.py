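"""Call differential regions on synthetic data with planted truth.

Builds the default benchmark: a 5-Mb CpG-desert genome tiled into 50,000
100-bp windows, 3 control vs 3 exposed pools with negative-binomial counts
(mean 50, dispersion 0.1), and 100 planted 3-window regions whose exposed
mean is raised 4-fold. Runs the window test and the seed-extend-merge
region caller, then scores the calls against the planted truth.
"""

from epiregion import (
    PipelineConfig,
    SimulationSpec,
    build_windows,
    call_regions,
    classify_regions,
    default_planted_regions,
    estimate_common_dispersion,
    filter_low_total,
    nb_exact_test,
    simulate_counts,
    simulate_genome,
    threshold_ladder,
)

spec = SimulationSpec(rng_seed=0)
spec.planted_regions = default_planted_regions(spec, n_regions=100,
                                               n_windows=3, fold_change=4.0)
genome = simulate_genome(spec)
windows = build_windows(genome, spec.window_size)
matrix, truth = simulate_counts(spec, windows)
matrix, removed = filter_low_total(matrix, 40)

dispersion = estimate_common_dispersion(matrix)
result = nb_exact_test(matrix, dispersion=dispersion)
config = PipelineConfig(rng_seed=0)
regions = call_regions(result, config)

called = regions.intervals()
hits = sum(
    any(c == tc and s < te and e > ts for c, s, e in called)
    for tc, ts, te in truth.planted_intervals
)
counts = classify_regions(regions)

print(f"windows tested: {len(result.windows)} ({removed} removed by 40-read filter)")
print(f"estimated dispersion phi: {dispersion.common_dispersion:.4f} (simulated 0.1)")
print(f"regions called at p<1e-6: {counts['all_window']} "
      f"({counts['multiple_window']} with >=2 significant windows)")
print(f"planted regions recovered: {hits}/100")
print("\nregion counts across seed thresholds (all vs multiple-window):")
print(threshold_ladder(result, config).to_string(index=False))
# The recovered fraction reflects per-window power at p<1e-6: a 4-fold
# change at mean 50 with dispersion 0.1 sits near the detection boundary
# for a 3-vs-3 pooled design.
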