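"""Bootstrap resampling and one-sided comparisons for small track sets.

Some stimulation conditions yield very few trackable spots (weak ligands
produce few complexes), so descriptor distributions are stabilized by
bootstrapping: the set of per-track descriptor values is resampled with
replacement many times (default 100,000 iterations) with a small sample
size (default 5), and the distribution of sample means is used for
visualization and comparison. Differences between conditions are assessed
with left-tailed t-tests (H1: mean of the first group is lower), matching
the expectation that lower-affinity ligands would reduce per-complex
descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BootstrapResult",
    "bootstrap_descriptor_means",
    "left_tailed_t_test",
    "TTestResult",
]

DEFAULT_N_ITERATIONS = 100_000
DEFAULT_SAMPLE_SIZE = 5


@dataclass
class BootstrapResult:
    """Bootstrap distribution of small-sample means for one condition/feature."""

    condition: str
    feature: str
    n_iterations: int
    sample_size: int
    seed: int
    means: np.ndarray

    @property
    def grand_mean(self) -> float:
        return float(self.means.mean())


@dataclass
class TTestResult:
    """One-sided Welch (or Student) t-test result."""

    statistic: float
    p_value: float
    degenerate: bool = False


def bootstrap_descriptor_means(
    descriptors,
    n_iter: int = DEFAULT_N_ITERATIONS,
    sample_size: int = DEFAULT_SAMPLE_SIZE,
    seed: int = 0,
    condition: str = "",
    feature: str = "",
) -> BootstrapResult:
    """Means of `n_iter` with-replacement samples of size `sample_size`."""
    values = np.asarray(descriptors, dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty descriptor set")
    if n_iter < 1 or sample_size < 1:
        raise ValueError("n_iter and sample_size must be positive")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_iter, sample_size))
    means = values[idx].mean(axis=1)
    return BootstrapResult(condition, feature, n_iter, sample_size, seed, means)


def left_tailed_t_test(
    sample_a, sample_b, equal_var: bool = False
) -> TTestResult:
    """Test H1: mean(sample_a) < mean(sample_b); Welch by default.

    Two identical zero-variance samples make the statistic undefined; by
    convention that returns p = 0.5 (no evidence either way), flagged
    ``degenerate``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    if a.std() == 0.0 and b.std() == 0.0:
        if a.mean() == b.mean():
            return TTestResult(np.nan, 0.5, degenerate=True)
        return TTestResult(-np.inf if a.mean() < b.mean() else np.inf,
                           0.0 if a.mean() < b.mean() else 1.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative="less")
    return TTestResult(float(res.statistic), float(res.pvalue))
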