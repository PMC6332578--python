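"""Self-contained simulation experiments exercising the full pipeline.

These functions generate synthetic data with planted truth, run the
estimators on it, and return summary numbers: estimator recovery and bias,
bootstrap-CI coverage, DM flatness under a mean-determined CV, and the
haploid/diploid noise contrast. They are used by the validation suite and
the reproduction script; each takes an explicit seed and is deterministic
given it.

The module also carries the published 2x2 housekeeping/ortholog gene counts
(human X vs autosomes, chicken chr1/chr4 complete and X-syntenic spans) as
input data for the chi-squared reproduction.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .cells import CellGroup
from .enrichment import ContingencyResult, chi2_2x2
from .noise import compute_dm
from .ratio import xaa_ratio_common_threshold, xaa_ratio_population
from .simulate import generate_annotation, generate_expression, recovery_config, sample_stratum

#: Published counts of (housekeeping, non-housekeeping) one-to-one-ortholog
#: genes in each focal set and its autosomal reference set: 53/360 X-linked
#: vs 2755/11649 autosomal housekeeping orthologs in human, and the chicken
#: chr1/chr4 tallies for the complete chromosomes and their X-syntenic spans.
PUBLISHED_HK_TABLES: dict[str, tuple[int, int, int, int]] = {
    "human_X_vs_autosomes": (53, 307, 2755, 8894),
    "chicken_chr1_complete": (316, 1299, 2384, 7456),
    "chicken_chr4_complete": (160, 675, 2540, 8080),
    "chicken_chr1_syntenic_span": (205, 860, 2495, 7895),
    "chicken_chr4_syntenic_span": (149, 653, 2551, 8102),
}


def published_depletion_tests(yates: bool = True) -> dict[str, ContingencyResult]:
    """Chi-squared tests on the published housekeeping/ortholog counts."""
    return {label: chi2_2x2(*counts, yates=yates, label=label)
            for label, counts in PUBLISHED_HK_TABLES.items()}


def _male_group(matrix) -> CellGroup:
    return CellGroup("E5", "TE", "male", tuple(matrix.columns))


def matched_estimate(
    true_ratio: float,
    seed: int,
    n_x: int = 2000,
    n_a: int = 10000,
    n_cells: int = 100,
    threshold: float = 10.0,
) -> float:
    """Matched-fraction point estimate on one generated male stratum."""
    cfg = recovery_config(true_ratio, n_x=n_x, n_a=n_a, n_cells=n_cells, seed=seed)
    ann, _ = generate_annotation(cfg)
    matrix, _, _ = generate_expression(cfg, ann)
    est = xaa_ratio_population(matrix, _male_group(matrix), ann, threshold, n_boot=0)
    return est.point


def estimator_pair(
    true_ratio: float,
    seed: int,
    n_x: int = 1000,
    n_a: int = 5000,
    n_cells: int = 50,
    threshold: float = 10.0,
) -> tuple[float, float]:
    """(matched, common-threshold) estimates on the same generated stratum."""
    cfg = recovery_config(true_ratio, n_x=n_x, n_a=n_a, n_cells=n_cells, seed=seed)
    ann, _ = generate_annotation(cfg)
    matrix, _, _ = generate_expression(cfg, ann)
    group = _male_group(matrix)
    matched = xaa_ratio_population(matrix, group, ann, threshold, n_boot=0)
    common = xaa_ratio_common_threshold(matrix, group, ann, threshold, n_boot=0)
    return matched.point, common.point


def bootstrap_coverage(
    n_sims: int,
    seed: int,
    true_ratio: float = 0.5,
    n_x: int = 2000,
    n_a: int = 10000,
    n_cells: int = 100,
    n_boot: int = 1000,
    level: float = 0.90,
) -> float:
    """Fraction of simulations whose bootstrap CI covers the planted ratio."""
    child = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31 - 1)
    covered = 0
    for s in child:
        cfg = recovery_config(true_ratio, n_x=n_x, n_a=n_a, n_cells=n_cells,
                              seed=int(s))
        ann, _ = generate_annotation(cfg)
        matrix, _, _ = generate_expression(cfg, ann)
        est = xaa_ratio_population(matrix, _male_group(matrix), ann, 10.0,
                                   n_boot=n_boot, level=level, seed=int(s) + 1)
        if est.ci_low <= true_ratio <= est.ci_high:
            covered += 1
    return covered / n_sims


def dm_flatness(n_genes: int = 2000, k: int = 20) -> tuple[float, float]:
    """DM under a CV that is a deterministic function of the mean alone.

    Builds a noise table whose CV decreases linearly along the mean ranking,
    computes DM, and returns (max |dm| over interior-window genes, Spearman
    rho between dm and mean over all genes). Both should be ~0: DM is meant
    to remove exactly this mean dependence.
    """
    import pandas as pd

    means = np.exp(np.linspace(0.0, 8.0, n_genes))
    cvs = 2.0 - 1.5 * np.arange(n_genes) / (n_genes - 1)
    noise = pd.DataFrame(
        {"mean": means, "cv": cvs},
        index=pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id"),
    )
    out = compute_dm(noise, k=k).sort_values("mean")
    half = k // 2
    interior = out.iloc[half : n_genes - (k - half)]
    max_abs = float(interior["dm"].abs().max())
    rho = float(spearmanr(out["dm"], out["mean"]).statistic)
    return max_abs, rho


def ploidy_cv_contrast(
    seed: int,
    n_genes: int = 1000,
    n_cells: int = 100,
    noise_a: float = 10.0,
    noise_b: float = 0.25,
    lognormal_mu: float = 2.5,
    lognormal_sigma: float = 1.0,
) -> tuple[float, float]:
    """(median CV at ploidy 1, median CV at ploidy 2) with identical
    per-allele parameters and identical total means."""
    rng = np.random.default_rng(seed)
    means = rng.lognormal(lognormal_mu, lognormal_sigma, n_genes)
    medians = []
    for ploidy in (1, 2):
        block = sample_stratum(means, np.full(n_genes, ploidy), noise_a,
                               np.full(n_genes, noise_b), n_cells, rng)
        cv = block.std(axis=1, ddof=1) / block.mean(axis=1)
        medians.append(float(np.median(cv)))
    return medians[0], medians[1]
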