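"""Per-gene expression noise (CV and DM) and between-set comparisons.

CV, the coefficient of variation, is the sample standard deviation of a
gene's expression across the cells of one stratum divided by its mean. CV is
confounded by expression level (the finite-number effect: lowly expressed
genes look noisier simply because fewer molecules are present), so the
second statistic, DM, measures a gene's distance to the median CV of genes
with comparable mean expression: genes are ranked by mean, each focal gene
gets a window of the k genes nearest in rank (k = 20 by default, 10 and 50
for sensitivity), and

    dm = focal CV - median(window CVs).

Larger DM means noisier than expected at that expression level. CV values of
two gene sets are compared by the ratio of their medians; DM, being already a
linear distance, is compared by subtraction of medians. Both comparisons
carry a 90% percentile-bootstrap CI (sets resampled independently, 1000
replicates) and a two-sided Mann-Whitney U p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bootstrap_median_pair_ci, mwu_two_sided
from .cells import CellGroup
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

#: Supported DM window sizes.
DM_WINDOWS = (10, 20, 50)


@dataclass(frozen=True)
class NoiseComparison:
    """Median-CV ratio or median-DM difference between two gene sets."""

    kind: str          # "cv_ratio" | "dm_difference"
    set_a: str
    set_b: str
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    mwu_p: float
    n_a: int
    n_b: int


def gene_noise_table(
    matrix: pd.DataFrame,
    cell_ids,
    gene_ids=None,
) -> pd.DataFrame:
    """Per-gene mean, sample SD (n-1 denominator) and CV over a cell group.

    Genes with zero mean are dropped with a log entry (their CV is
    undefined). Requires at least two cells.
    """
    cells = list(cell_ids)
    if len(cells) < 2:
        raise DegenerateInputError("noise statistics require at least 2 cells")
    sub = matrix[cells]
    if gene_ids is not None:
        sub = sub.loc[list(gene_ids)]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    zero = mean == 0.0
    if zero.any():
        logger.info("%d gene(s) with zero mean dropped from noise table", int(zero.sum()))
    out = pd.DataFrame({"mean": mean[~zero], "sd": sd[~zero]})
    out["cv"] = out["sd"] / out["mean"]
    out.index.name = "gene_id"
    return out


def compute_dm(noise: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Add a ``dm`` column to a pooled noise table.

    Genes are sorted by mean expression (rank ties broken by gene id). Each
    focal gene's window is the k genes nearest in rank, the focal gene
    excluded; at the edges of the ranking the window is shifted inward so it
    always holds exactly k genes. The result is independent of the input row
    order, and the window construction depends only on ranks, so globally
    rescaling expression leaves DM unchanged.
    """
    n = len(noise)
    if n <= k:
        raise DegenerateInputError(f"DM with k={k} needs more than {k} genes, got {n}")
    # stable sort after ordering the index makes rank ties break by gene id
    ordered = noise.loc[noise.index.sort_values()].sort_values("mean", kind="mergesort")
    cv = ordered["cv"].to_numpy()
    dm = np.empty(n)
    half = k // 2
    for i in range(n):
        lo = min(max(i - half, 0), n - 1 - k)
        window = np.concatenate([cv[lo:i], cv[i + 1 : lo + k + 1]])
        dm[i] = cv[i] - np.median(window)
    out = ordered.copy()
    out["dm"] = dm
    out["window_k"] = k
    return out.loc[noise.index]


def cv_ratio(
    noise_x: pd.DataFrame,
    noise_a: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.90,
    seed=None,
    set_a: str = "X",
    set_b: str = "autosomal",
) -> NoiseComparison:
    """Ratio of median CVs between two gene sets (X vs autosomal by default)."""
    if len(noise_x) == 0 or len(noise_a) == 0:
        raise DegenerateInputError("cv_ratio requires two non-empty noise tables")
    cv_a = noise_x["cv"].to_numpy()
    cv_b = noise_a["cv"].to_numpy()
    med_b = float(np.median(cv_b))
    if med_b == 0.0:
        raise DegenerateInputError("median CV of the reference set is zero")
    point = float(np.median(cv_a)) / med_b
    ci_low, ci_high = bootstrap_median_pair_ci(
        cv_a, cv_b, combine=lambda ma, mb: ma / mb, n_boot=n_boot, level=level, seed=seed
    )
    return NoiseComparison(
        kind="cv_ratio", set_a=set_a, set_b=set_b, point=point,
        ci_low=ci_low, ci_high=ci_high, n_boot=n_boot,
        mwu_p=mwu_two_sided(cv_a, cv_b), n_a=len(cv_a), n_b=len(cv_b),
    )


def dm_difference(
    noise_a: pd.DataFrame,
    noise_b: pd.DataFrame,
    n_boot: int = 1000,
    level: float = 0.90,
    seed=None,
    set_a: str = "X",
    set_b: str = "autosomal",
) -> NoiseComparison:
    """Difference of median DMs between two gene sets.

    Both tables must carry a ``dm`` column computed on the same pooled
    ranking (see :func:`compute_dm`).
    """
    if "dm" not in noise_a.columns or "dm" not in noise_b.columns:
        raise ValueError("dm_difference requires tables with a dm column")
    if len(noise_a) == 0 or len(noise_b) == 0:
        raise DegenerateInputError("dm_difference requires two non-empty noise tables")
    dm_a = noise_a["dm"].to_numpy()
    dm_b = noise_b["dm"].to_numpy()
    point = float(np.median(dm_a) - np.median(dm_b))
    ci_low, ci_high = bootstrap_median_pair_ci(
        dm_a, dm_b, combine=lambda ma, mb: ma - mb, n_boot=n_boot, level=level, seed=seed
    )
    return NoiseComparison(
        kind="dm_difference", set_a=set_a, set_b=set_b, point=point,
        ci_low=ci_low, ci_high=ci_high, n_boot=n_boot,
        mwu_p=mwu_two_sided(dm_a, dm_b), n_a=len(dm_a), n_b=len(dm_b),
    )


def noise_for_group(
    matrix: pd.DataFrame,
    group: CellGroup,
    gene_ids=None,
) -> pd.DataFrame:
    """Convenience wrapper: noise table over a stratum's cells."""
    return gene_noise_table(matrix, group.cell_ids, gene_ids)
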