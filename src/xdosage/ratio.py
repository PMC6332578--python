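"""X:AA expression-ratio estimation with fraction-matched gene selection.

The dosage statistic is the ratio of the median expression of X-linked genes
to that of autosomal genes. Comparing "actively expressed" genes chosen by a
single RPKM threshold on both chromosome classes overestimates the ratio
whenever the true ratio is below 1, because the threshold cuts deeper into
the (down-shifted) X distribution. The unbiased alternative implemented here
selects the fraction x% of X-linked genes whose mean expression reaches the
threshold T, and then the same fraction x% of autosomal genes taken from the
top of the autosomal mean-expression ranking. Both estimators are provided;
their disagreement under a true ratio < 1 is itself a result of interest.

Point estimates carry a 90% percentile-bootstrap confidence interval of the
median ratio (the selected X and autosomal gene sets are resampled with
replacement independently, 1000 replicates by default) and a two-sided
Mann-Whitney U p-value comparing the selected X and autosomal expression
values (rejecting implies a ratio different from 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bootstrap_median_pair_ci, mwu_two_sided
from .cells import CellGroup
from .errors import DegenerateInputError
from .io import AUTOSOMES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchedGeneSets:
    """Fraction-matched X and autosomal gene selections at one threshold."""

    threshold: float
    x_fraction: float
    selected_x: tuple[str, ...]
    selected_a: tuple[str, ...]


@dataclass(frozen=True)
class RatioEstimate:
    """Median-X / median-A ratio with bootstrap CI and rank-test p-value."""

    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    mwu_p: float
    n_x: int
    n_a: int


@dataclass(frozen=True)
class PerCellRatioSummary:
    """Per-cell X:AA ratios within one stratum, summarised by median and range."""

    ratios: pd.Series = field(repr=False)
    median: float
    minimum: float
    maximum: float
    n_skipped: int


def _round_half_away(x: float) -> int:
    """round-half-away-from-zero, e.g. 2.5 -> 3 (Python's round() would give 2)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def compute_expressed_fraction(x_means: pd.Series, threshold: float) -> float:
    """Fraction of X-linked genes whose mean expression reaches the threshold."""
    if len(x_means) == 0:
        raise DegenerateInputError("no X-linked genes; expressed fraction undefined")
    return float((x_means >= threshold).sum()) / float(len(x_means))


def select_matched_gene_sets(
    means: pd.Series,
    annotation: pd.DataFrame,
    threshold: float = 10.0,
    autosome: str | None = None,
) -> MatchedGeneSets:
    """Select X-linked genes >= threshold and the same top fraction of autosomes.

    ``means`` maps gene id to mean RPKM over the cells under study. Only
    genes with a one-to-one chicken ortholog enter either set. When
    ``autosome`` is given, the autosomal pool is restricted to that single
    chromosome (per-autosome estimates); otherwise it is chromosomes 1-22.
    Autosomal ranking ties are broken lexicographically by gene id so the
    selection is deterministic.
    """
    ann = annotation.loc[annotation.index.intersection(means.index)]
    universe = ann.index[ann["one2one_chicken"]]
    ann = ann.loc[universe]
    x_genes = ann.index[ann["chromosome"] == "X"]
    if autosome is None:
        a_genes = ann.index[ann["chromosome"].isin(AUTOSOMES)]
    else:
        a_genes = ann.index[ann["chromosome"] == autosome]
    if len(x_genes) == 0 or len(a_genes) == 0:
        raise DegenerateInputError(
            "matched selection requires both X-linked and autosomal genes "
            "in the ortholog universe"
        )
    x_means = means.loc[x_genes]
    x_fraction = compute_expressed_fraction(x_means, threshold)
    if x_fraction == 0.0:
        raise DegenerateInputError(
            f"no expressed X-linked genes at threshold {threshold} RPKM"
        )
    selected_x = tuple(sorted(x_means.index[x_means >= threshold]))
    n_a = max(1, _round_half_away(x_fraction * len(a_genes)))
    a_means = means.loc[a_genes]
    a_ranked = pd.DataFrame(
        {"gene_id": a_means.index.astype(str), "mean": a_means.to_numpy()}
    ).sort_values(["mean", "gene_id"], ascending=[False, True])
    selected_a = tuple(a_ranked["gene_id"].head(n_a))
    return MatchedGeneSets(
        threshold=float(threshold),
        x_fraction=x_fraction,
        selected_x=selected_x,
        selected_a=selected_a,
    )


def bootstrap_ratio_ci(
    selected_x_values,
    selected_a_values,
    n_boot: int = 1000,
    level: float = 0.90,
    seed=None,
) -> tuple[float, float]:
    """Percentile-bootstrap CI for median(X)/median(A); deterministic given seed."""
    return bootstrap_median_pair_ci(
        selected_x_values,
        selected_a_values,
        combine=lambda mx, ma: mx / ma,
        n_boot=n_boot,
        level=level,
        seed=seed,
    )


def mwu_vs_unity(selected_x_values, selected_a_values) -> float:
    """Two-sided Mann-Whitney U on the selected X vs autosomal expression values."""
    return mwu_two_sided(selected_x_values, selected_a_values)


def wilcoxon_vs_unity(per_cell_ratios) -> float:
    """One-sample alternative: two-sided Wilcoxon signed-rank of per-cell
    ratios against 1 (sensitivity analysis for the default two-sample test)."""
    from scipy import stats

    ratios = np.asarray(per_cell_ratios, dtype=float)
    if ratios.size == 0:
        raise DegenerateInputError("no per-cell ratios to test")
    if np.all(ratios == 1.0):
        return 1.0
    return float(stats.wilcoxon(ratios - 1.0, alternative="two-sided").pvalue)


def reselection_bootstrap_ci(
    means: pd.Series,
    annotation: pd.DataFrame,
    threshold: float,
    n_boot: int = 1000,
    level: float = 0.90,
    seed=None,
) -> tuple[float, float]:
    """Sensitivity variant of the CI: re-run gene selection in every replicate.

    The X and autosomal ortholog universes are resampled with replacement and
    the matched selection plus median ratio recomputed per replicate, so the
    interval also reflects uncertainty of the selection step itself.
    Replicates whose resampled expressed fraction is zero are dropped.
    """
    ann = annotation.loc[annotation.index.intersection(means.index)]
    ann = ann.loc[ann["one2one_chicken"]]
    x_means = means.loc[ann.index[ann["chromosome"] == "X"]].to_numpy()
    a_means = means.loc[ann.index[ann["chromosome"].isin(AUTOSOMES)]].to_numpy()
    if x_means.size == 0 or a_means.size == 0:
        raise DegenerateInputError("reselection bootstrap requires X and A genes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        xs = rng.choice(x_means, size=x_means.size, replace=True)
        avs = rng.choice(a_means, size=a_means.size, replace=True)
        sel_x = xs[xs >= threshold]
        if sel_x.size == 0:
            continue
        n_a = max(1, _round_half_away(sel_x.size / xs.size * avs.size))
        sel_a = np.sort(avs)[::-1][:n_a]
        med_a = np.median(sel_a)
        if med_a == 0:
            continue
        reps.append(np.median(sel_x) / med_a)
    if not reps:
        raise DegenerateInputError("every reselection replicate was degenerate")
    if len(reps) < n_boot:
        logger.warning("%d of %d reselection replicates dropped as degenerate",
                       n_boot - len(reps), n_boot)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(reps, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _group_means(matrix: pd.DataFrame, group: CellGroup) -> pd.Series:
    missing = [c for c in group.cell_ids if c not in matrix.columns]
    if missing:
        raise ValueError(f"cells absent from matrix: {missing[:3]}...")
    return matrix[list(group.cell_ids)].mean(axis=1)


def _estimate_from_values(
    x_values: np.ndarray,
    a_values: np.ndarray,
    n_boot: int,
    level: float,
    seed,
) -> RatioEstimate:
    med_a = float(np.median(a_values))
    if med_a == 0.0:
        raise DegenerateInputError("median autosomal expression is zero; ratio undefined")
    point = float(np.median(x_values)) / med_a
    if n_boot >= 1:
        ci_low, ci_high = bootstrap_ratio_ci(x_values, a_values, n_boot, level, seed)
        if not (ci_low <= point <= ci_high):
            logger.warning(
                "bootstrap CI (%.4g, %.4g) does not bracket the point estimate %.4g",
                ci_low, ci_high, point,
            )
    else:
        ci_low = ci_high = float("nan")
    p = mwu_vs_unity(x_values, a_values)
    return RatioEstimate(
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=max(n_boot, 0),
        mwu_p=p,
        n_x=int(len(x_values)),
        n_a=int(len(a_values)),
    )


def xaa_ratio_population(
    matrix: pd.DataFrame,
    group: CellGroup,
    annotation: pd.DataFrame,
    threshold: float = 10.0,
    n_boot: int = 1000,
    level: float = 0.90,
    seed=None,
) -> RatioEstimate:
    """Population-level X:AA ratio for one stratum with fraction matching.

    Gene means are taken over the group's cells; the matched selection and
    the median ratio follow :func:`select_matched_gene_sets`.
    """
    means = _group_means(matrix, group)
    sets = select_matched_gene_sets(means, annotation, threshold)
    return _estimate_from_values(
        means.loc[list(sets.selected_x)].to_numpy(),
        means.loc[list(sets.selected_a)].to_numpy(),
        n_boot, level, seed,
    )


def xaa_ratio_common_threshold(
    matrix: pd.DataFrame,
    group: CellGroup,
    annotation: pd.DataFrame,
    threshold: float = 10.0,
    n_boot: int = 1000,
    level: float = 0.90,
    seed=None,
) -> RatioEstimate:
    """X:AA ratio with a single RPKM cut-off on both classes (biased when < 1)."""
    means = _group_means(matrix, group)
    ann = annotation.loc[annotation.index.intersection(means.index)]
    ann = ann.loc[ann["one2one_chicken"]]
    x_means = means.loc[ann.index[ann["chromosome"] == "X"]]
    a_means = means.loc[ann.index[ann["chromosome"].isin(AUTOSOMES)]]
    x_sel = x_means[x_means >= threshold]
    a_sel = a_means[a_means >= threshold]
    if len(x_sel) == 0 or len(a_sel) == 0:
        raise DegenerateInputError(
            f"no genes reach {threshold} RPKM on X or autosomes in this stratum"
        )
    return _estimate_from_values(x_sel.to_numpy(), a_sel.to_numpy(), n_boot, level, seed)


def xaa_ratio_per_cell(
    matrix: pd.DataFrame,
    group: CellGroup,
    annotation: pd.DataFrame,
    threshold: float = 10.0,
) -> PerCellRatioSummary:
    """X:AA ratio recomputed within each single cell of a stratum.

    The fraction-matched selection uses each cell's own RPKM values. Cells
    where no X-linked gene reaches the threshold (or the autosomal median is
    zero) are skipped with a log entry; if every cell is skipped an error is
    raised.
    """
    ratios: dict[str, float] = {}
    n_skipped = 0
    for cell in group.cell_ids:
        values = matrix[cell]
        try:
            sets = select_matched_gene_sets(values, annotation, threshold)
            med_a = float(np.median(values.loc[list(sets.selected_a)]))
            if med_a == 0.0:
                raise DegenerateInputError("zero autosomal median")
            ratios[cell] = float(np.median(values.loc[list(sets.selected_x)])) / med_a
        except DegenerateInputError as exc:
            logger.info("cell %s skipped in per-cell ratio: %s", cell, exc)
            n_skipped += 1
    if not ratios:
        raise DegenerateInputError(
            f"all {group.n_cells} cells of {group.label} skipped; per-cell ratio undefined"
        )
    series = pd.Series(ratios, name="xaa_ratio")
    return PerCellRatioSummary(
        ratios=series,
        median=float(series.median()),
        minimum=float(series.min()),
        maximum=float(series.max()),
        n_skipped=n_skipped,
    )


def xaa_ratio_per_autosome(
    matrix: pd.DataFrame,
    group: CellGroup,
    annotation: pd.DataFrame,
    threshold: float = 10.0,
    n_boot: int = 1000,
    level: float = 0.90,
    seed=None,
) -> dict[str, RatioEstimate]:
    """One X:AA estimate per autosome, fraction-matched against that autosome.

    Autosomes with no qualifying genes are absent from the result (not zero).
    """
    means = _group_means(matrix, group)
    rng = np.random.default_rng(seed)
    out: dict[str, RatioEstimate] = {}
    for chrom in AUTOSOMES:
        try:
            sets = select_matched_gene_sets(means, annotation, threshold, autosome=chrom)
            out[chrom] = _estimate_from_values(
                means.loc[list(sets.selected_x)].to_numpy(),
                means.loc[list(sets.selected_a)].to_numpy(),
                n_boot, level, rng,
            )
        except DegenerateInputError as exc:
            logger.info("autosome %s skipped: %s", chrom, exc)
    return out
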