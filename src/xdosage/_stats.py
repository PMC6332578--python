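"""Shared statistical primitives: paired bootstrap of medians, Mann-Whitney U."""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import stats


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def bootstrap_median_pair_ci(
    values_a: np.ndarray,
    values_b: np.ndarray,
    combine: Callable[[np.ndarray, np.ndarray], np.ndarray],
    n_boot: int = 1000,
    level: float = 0.90,
    seed=None,
) -> tuple[float, float]:
    """Percentile bootstrap CI for combine(median(A*), median(B*)).

    The two samples are resampled with replacement independently; the CI is
    the (alpha/2, 1-alpha/2) percentile pair of the replicate statistics,
    computed with linear interpolation between order statistics
    (numpy.quantile default).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("bootstrap requires non-empty samples")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = _as_rng(seed)
    idx_a = rng.integers(0, a.size, size=(n_boot, a.size))
    idx_b = rng.integers(0, b.size, size=(n_boot, b.size))
    med_a = np.median(a[idx_a], axis=1)
    med_b = np.median(b[idx_b], axis=1)
    reps = combine(med_a, med_b)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def mwu_two_sided(x, y, max_exact_n: int = 20) -> float:
    """Two-sided Mann-Whitney U p-value.

    The exact null distribution is used when both samples have at most
    ``max_exact_n`` observations and no value is tied (within or across
    samples); otherwise the normal approximation with tie correction and no
    continuity correction is used, so identical samples give p = 1 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size <= max_exact_n and y.size <= max_exact_n and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.pvalue)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.pvalue)
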