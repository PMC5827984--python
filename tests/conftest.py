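import numpy as np
import pytest

from epiregion import (
    GenomeIndex,
    PipelineConfig,
    SampleDesign,
    WindowCountMatrix,
    build_windows,
)


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def small_genome():
    """Two tiny chromosomes with known CpG placement."""
    return GenomeIndex(
        {
            "chr1": "ACGT" * 250,        # 1000 bp, one CG per 4 bp
            "chr2": "AT" * 150 + "CG" * 2 + "A",  # 305 bp
        }
    )


@pytest.fixture
def design_3v3():
    return SampleDesign.balanced(3)


def make_matrix(counts, design=None, genome_len=None, window_size=100):
    """WindowCountMatrix on a synthetic chr1 grid from a counts array."""
    counts = np.asarray(counts, dtype=np.int64)
    n_w, n_s = counts.shape
    if design is None:
        design = SampleDesign.balanced(n_s // 2)
    genome_len = genome_len or n_w * window_size
    genome = GenomeIndex({"chr1": "A" * genome_len})
    windows = build_windows(genome, window_size)[:n_w]
    return WindowCountMatrix(windows, counts, design, counts.sum(axis=0))


@pytest.fixture
def matrix_factory():
    return make_matrix
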