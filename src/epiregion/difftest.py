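"""Per-window two-group differential-coverage testing.

The test is an exact conditional negative-binomial test with a single
genome-wide (common) dispersion phi, parameterized throughout as

    Var(Y) = mu + phi * mu^2        (NB size r = 1/phi)

Counts are first scaled to a common library size, pools within a group are
collapsed by summation, and the two-sided p-value for a window is the
probability, conditional on the window total, of any group split at least
as extreme as the observed one — "at least as extreme" meaning its
conditional probability does not exceed that of the observed split (ties
included). With phi = 0 the group sums are Poisson and the conditional
distribution degenerates to a binomial split with proportion equal to the
control group's size fraction.

This is a calibrated stand-in for an edgeR-style exact test: the contract
is a uniform null p distribution and controlled type-I error, not bit
equivalence with any particular external implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .counts import CONTROL, EXPOSED, SampleDesign, WindowCountMatrix
from .genome import Window


@dataclass(frozen=True)
class DispersionEstimate:
    """Common NB dispersion phi with Var = mu + phi mu^2."""

    common_dispersion: float
    method: str
    n_windows_used: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.common_dispersion) or self.common_dispersion < 0:
            raise ValueError(f"dispersion must be finite and >= 0, got {self.common_dispersion}")


@dataclass
class WindowTestResult:
    """Per-window differential test output, aligned with ``windows``."""

    windows: list[Window]
    p_value: np.ndarray
    log2_fold_change: np.ndarray  # exposed over control, normalized means
    mean_control: np.ndarray
    mean_exposed: np.ndarray
    fdr_q: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [w.chrom for w in self.windows],
                "start": [w.start for w in self.windows],
                "end": [w.end for w in self.windows],
                "p": self.p_value,
                "q": self.fdr_q,
                "log2FC": self.log2_fold_change,
                "mean_control": self.mean_control,
                "mean_exposed": self.mean_exposed,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def normalize_library_sizes(matrix: WindowCountMatrix) -> np.ndarray:
    """Per-sample scaling factors proportional to library size.

    Factors have geometric mean 1; dividing a sample's counts by its factor
    puts all samples on the common (geometric-mean) library size — a
    counts-per-million-style normalization without a fixed denominator.
    """
    sizes = np.asarray(matrix.library_sizes, dtype=float)
    for j, size in enumerate(sizes):
        if size <= 0:
            raise ValueError(
                f"sample {matrix.design.sample_ids[j]!r} has zero library size"
            )
    log_sizes = np.log(sizes)
    return np.exp(log_sizes - log_sizes.mean())


def normalized_counts(matrix: WindowCountMatrix) -> np.ndarray:
    return matrix.counts / normalize_library_sizes(matrix)


def estimate_common_dispersion(
    matrix: WindowCountMatrix, design: SampleDesign | None = None
) -> DispersionEstimate:
    """Median-of-moments common dispersion, pooled across windows.

    Within each group, every window gives a moment ratio
    ``(s^2 - m) / m^2`` on normalized counts; the median over windows is
    robust to the minority of truly differential windows. With few
    replicates the median of the ratio is badly biased downward — the
    sample variance is approximately ``(mu + phi mu^2) chi2_{n-1}/(n-1)``
    and the chi-square median sits well below its mean (0.693 of it at
    n = 3) — so the median ratio ``rho`` is inverted through

        rho ~= c phi + (c - 1)/m,   c = median(chi2_{n-1})/(n-1),

    evaluated at the median window mean. Per-group estimates are averaged
    and clamped at zero, so under-dispersed data give phi = 0. Without the
    correction the estimate runs ~30% low at n = 3 and the downstream
    exact test loses its type-I error control.
    """
    design = design or matrix.design
    norm = matrix.counts / normalize_library_sizes(matrix)
    group_phis = []
    n_used = 0
    for group in (CONTROL, EXPOSED):
        idx = design.group_indices(group)
        if len(idx) < 2:
            raise ValueError(f"need >=2 samples in group {group!r} to estimate dispersion")
        sub = norm[:, idx]
        n = len(idx)
        c = sps.chi2.median(n - 1) / (n - 1)
        m = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        ok = m > 0
        n_used += int(ok.sum())
        if ok.any():
            rho = float(np.median((s2[ok] - m[ok]) / m[ok] ** 2))
            m_med = float(np.median(m[ok]))
            group_phis.append((rho + (1.0 - c) / m_med) / c)
        else:
            group_phis.append(0.0)
    phi = max(0.0, float(np.mean(group_phis)))
    return DispersionEstimate(phi, "moments-median-debiased", n_used)


def _conditional_log_pmf(total: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log conditional pmf of the group-A sum given the window total.

    Group sums of iid NB(mean mu, dispersion phi) samples are NB with size
    n/phi and the same success probability, so the conditional distribution
    of the split is free of mu once the shared success probability cancels;
    any positive mu gives identical conditionals and mu = total/(n_a+n_b)
    is used for numerical balance.
    """
    a = np.arange(total + 1)
    if phi == 0.0:
        return sps.binom.logpmf(a, total, n_a / (n_a + n_b))
    mu = max(total, 1) / (n_a + n_b)
    r_a, r_b = n_a / phi, n_b / phi
    p_a = r_a / (r_a + n_a * mu)
    p_b = r_b / (r_b + n_b * mu)
    log_pmf = sps.nbinom.logpmf(a, r_a, p_a) + sps.nbinom.logpmf(total - a, r_b, p_b)
    # normalize to the conditional distribution
    mx = log_pmf.max()
    log_pmf -= mx + np.log(np.exp(log_pmf - mx).sum())
    return log_pmf


def exact_split_p(total: int, observed_a: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact conditional p for one window.

    Sum of the conditional probabilities of every split whose probability
    is <= that of the observed split (relative tie tolerance 1e-12),
    capped at 1. A window with zero total returns p = 1 by convention.
    """
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if total == 0:
        return 1.0
    log_pmf = _conditional_log_pmf(total, n_a, n_b, phi)
    pmf = np.exp(log_pmf)
    p_obs = pmf[observed_a]
    p = pmf[pmf <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def nb_exact_test(
    matrix: WindowCountMatrix,
    design: SampleDesign | None = None,
    dispersion: DispersionEstimate | float | None = None,
) -> WindowTestResult:
    """Exact NB conditional test for every window of the matrix.

    Counts are scaled to the common library size and rounded to integer
    pseudo-counts, group sums are formed, and the conditional split test is
    applied per window. The conditional pmf depends only on the window
    total (for fixed group sizes and phi), so it is cached across windows.
    """
    design = design or matrix.design
    if dispersion is None:
        dispersion = estimate_common_dispersion(matrix, design)
    phi = dispersion.common_dispersion if isinstance(dispersion, DispersionEstimate) else float(dispersion)
    if phi < 0:
        raise ValueError("dispersion must be >= 0")

    idx_ctrl = design.group_indices(CONTROL)
    idx_exp = design.group_indices(EXPOSED)
    n_a, n_b = len(idx_ctrl), len(idx_exp)

    norm = matrix.counts / normalize_library_sizes(matrix)
    pseudo = np.rint(norm).astype(np.int64)
    y_a = pseudo[:, idx_ctrl].sum(axis=1)
    y_b = pseudo[:, idx_exp].sum(axis=1)
    totals = y_a + y_b

    cache: dict[int, np.ndarray] = {}
    p_values = np.ones(matrix.n_windows)
    for i in range(matrix.n_windows):
        t = int(totals[i])
        if t == 0:
            continue
        pmf = cache.get(t)
        if pmf is None:
            pmf = np.exp(_conditional_log_pmf(t, n_a, n_b, phi))
            cache[t] = pmf
        p_obs = pmf[y_a[i]]
        p_values[i] = min(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum(), 1.0)

    mean_control = norm[:, idx_ctrl].mean(axis=1)
    mean_exposed = norm[:, idx_exp].mean(axis=1)
    log2fc = np.log2((mean_exposed + 0.5) / (mean_control + 0.5))
    return WindowTestResult(
        windows=matrix.windows,
        p_value=p_values,
        log2_fold_change=log2fc,
        mean_control=mean_control,
        mean_exposed=mean_exposed,
        fdr_q=bh_fdr(p_values),
    )


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
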