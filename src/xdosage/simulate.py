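"""Synthetic single-cell RPKM data with known dosage and noise ground truth.

The generator emulates the statistical shape of a preimplantation-embryo
single-cell RNA-seq study: ~12,000 human genes with one-to-one chicken
orthologs (360 X-linked in expectation), cells from embryonic days E3-E7
split into trophectoderm / primitive-endoderm / epiblast lineages (E3-E4
predate lineage segregation and are labelled "prelineage"), and both sexes.

Model
-----
Each gene g draws a base mean m_g from LogNormal(mu, sigma). In a stratum
(day, lineage, sex) the expected expression is m_g, scaled by the planted
X:AA ratio r(day, sex) for X-linked genes; Y-linked genes are flat at
``y_male_mean`` in males and exactly zero in females. A cell's value is the
sum over `ploidy` independent allele draws, each Gamma-distributed with mean
(stratum mean / ploidy) and a variance chosen so that the total squared
coefficient of variation at diploidy is

    CV^2 = noise_a / mean + b_g,        b_g = noise_b * (hk_noise_factor if
                                               housekeeping else 1)

i.e. an intrinsic 1/mean term plus an extrinsic floor, the floor reduced for
housekeeping genes. Because allele draws are independent, a haploid gene
keeps the full per-allele variance (CV^2 = noise_a/mean + 2 b_g) while a
diploid gene averages half of it away — the ploidy-noise contrast the noise
analyses rely on.

Annotation side: housekeeping flags are Bernoulli per chromosome
(hk_probability), one-to-one ortholog flags are Bernoulli
(ortholog_probability), X-linked orthologs map into X-syntenic blocks on
chicken chromosomes 1 and 4, and autosomal orthologs scatter uniformly over
the chicken autosomes.

All randomness flows from a single seed through independent named streams
(annotation / expression), so the two tables are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import (
    AUTOSOMES,
    write_cell_metadata,
    write_expression_matrix,
    write_gene_annotation,
)

DAYS = ("E3", "E4", "E5", "E6", "E7")

#: Chicken chromosome length used for uniform gene placement (bp).
_CHICKEN_CHROM_LEN = 50_000_000
#: Coordinates of the X-syntenic block on chicken chr1 and chr4.
_SYNTENIC_BLOCK = (5_000_000, 25_000_000)
_GENE_LEN = 2_000
_GENE_SPACING = 3_000


def _default_gene_counts() -> dict[str, int]:
    # ~662 genes x 22 autosomes and 450 X genes; with ortholog_probability
    # 0.8 this gives ~11.6k autosomal and ~360 X-linked orthologs in
    # expectation, the universe size of the emulated study.
    counts = {str(i): 662 for i in range(1, 23)}
    counts["X"] = 450
    counts["Y"] = 40
    return counts


def _default_hk_probability() -> dict[str, float]:
    # 53/360 on X and 2755/11649 on autosomes.
    probs = {str(i): 0.2365 for i in range(1, 23)}
    probs["X"] = 0.147
    probs["Y"] = 0.0
    return probs


def _default_true_ratio() -> dict[tuple[str, str], float]:
    # Males at 0.5 throughout; females decline from 0.75 at E3 to 0.5 at E7.
    female = {"E3": 0.75, "E4": 0.6875, "E5": 0.625, "E6": 0.5625, "E7": 0.5}
    out: dict[tuple[str, str], float] = {}
    for day in DAYS:
        out[(day, "male")] = 0.5
        out[(day, "female")] = female[day]
    return out


def default_strata() -> list[tuple[str, str, str]]:
    """The full (day, lineage, sex) grid: E3/E4 prelineage, E5-E7 x TE/PE/EPI."""
    strata = []
    for day in DAYS:
        lineages = ("prelineage",) if day in ("E3", "E4") else ("TE", "PE", "EPI")
        for lin in lineages:
            for sex in ("male", "female"):
                strata.append((day, lin, sex))
    return strata


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults emulate the source study."""

    n_genes_per_chromosome: Mapping[str, int] = field(default_factory=_default_gene_counts)
    strata: list[tuple[str, str, str]] = field(default_factory=default_strata)
    n_cells_per_stratum: int = 70        # ~1540 cells over the 22-stratum grid
    lognormal_mu: float = 2.0            # natural-log scale of gene means (RPKM)
    lognormal_sigma: float = 1.5
    noise_a: float = 10.0                # intrinsic CV^2 term: noise_a / mean
    noise_b: float = 0.25                # extrinsic CV^2 floor at diploidy
    hk_noise_factor: float = 0.5         # multiplier on noise_b for housekeeping genes
    hk_probability: Mapping[str, float] = field(default_factory=_default_hk_probability)
    true_ratio: Mapping[tuple[str, str], float] = field(default_factory=_default_true_ratio)
    y_male_mean: float = 5.0             # RPKM of Y-linked genes in male cells
    ortholog_probability: float = 0.8
    chicken_autosomes: tuple[str, ...] = tuple(str(i) for i in range(1, 11))
    x_syntenic_chr1_fraction: float = 0.7  # X orthologs on chicken chr1 vs chr4
    embryo_size: int = 10                # cells per synthetic embryo
    seed: int = 0

    def __post_init__(self) -> None:
        for chrom, p in self.hk_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"hk_probability[{chrom}] out of [0,1]")
        if not 0.0 <= self.ortholog_probability <= 1.0:
            raise ValueError("ortholog_probability out of [0,1]")
        if self.noise_a < 0 or self.noise_b < 0:
            raise ValueError("noise coefficients must be >= 0")
        for key, r in self.true_ratio.items():
            if not r > 0:
                raise ValueError(f"true_ratio[{key}] must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        """Build a config from a YAML document mirroring the field names.

        ``true_ratio`` may be written nested as ``{sex: {day: r}}`` or as a
        single number applied to every (day, sex); ``hk_probability`` and
        ``n_genes_per_chromosome`` accept either a mapping or a scalar
        applied to all chromosomes.
        """
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key, value in doc.items():
            if key == "true_ratio":
                if isinstance(value, Mapping):
                    ratio: dict[tuple[str, str], float] = {}
                    for sex, per_day in value.items():
                        if isinstance(per_day, Mapping):
                            for day, r in per_day.items():
                                ratio[(day, sex)] = float(r)
                        else:
                            for day in DAYS:
                                ratio[(day, sex)] = float(per_day)
                    kwargs[key] = ratio
                else:
                    kwargs[key] = {(d, s): float(value)
                                   for d in DAYS for s in ("male", "female")}
            elif key == "hk_probability" and not isinstance(value, Mapping):
                kwargs[key] = {c: float(value) for c in _default_hk_probability()}
            elif key == "n_genes_per_chromosome" and not isinstance(value, Mapping):
                kwargs[key] = {c: int(value) for c in _default_gene_counts()}
            elif key == "strata":
                kwargs[key] = [tuple(s) for s in value]
            elif key == "chicken_autosomes":
                kwargs[key] = tuple(str(c) for c in value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests: planted ratios, means and ploidy."""

    true_ratio: Mapping[tuple[str, str], float]
    base_means: pd.Series | None = None          # per-gene base mean (RPKM)
    cell_sex: pd.Series | None = None            # per-cell true sex
    ploidy: pd.DataFrame | None = None           # genes x {male, female} allele counts
    hk_probability: Mapping[str, float] | None = None

    def write(self, path: str | Path) -> None:
        rows = [{"day": d, "sex": s, "true_xaa_ratio": r}
                for (d, s), r in sorted(self.true_ratio.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _rng_for(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def generate_annotation(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a gene annotation table with planted housekeeping depletion."""
    rng = _rng_for(config, 0)
    if config.n_genes_per_chromosome.get("X", 0) < 1:
        raise ValueError("generator requires at least one X-linked gene")
    if not any(config.n_genes_per_chromosome.get(c, 0) > 0 for c in AUTOSOMES):
        raise ValueError("generator requires autosomal genes")

    records = []
    for chrom in sorted(config.n_genes_per_chromosome):
        n = int(config.n_genes_per_chromosome[chrom])
        hk_p = config.hk_probability.get(chrom, 0.0)
        hk_flags = rng.random(n) < hk_p
        ortho_flags = rng.random(n) < (
            config.ortholog_probability if chrom != "Y" else 0.0
        )
        for i in range(n):
            start = 1 + i * _GENE_SPACING
            rec = {
                "gene_id": f"G{chrom}_{i:05d}",
                "chromosome": chrom,
                "start": start,
                "end": start + _GENE_LEN - 1,
                "housekeeping": bool(hk_flags[i]),
                "one2one_chicken": bool(ortho_flags[i]),
                "chicken_chromosome": None,
                "chicken_start": pd.NA,
                "chicken_end": pd.NA,
                "x_syntenic": False,
            }
            if rec["one2one_chicken"]:
                if chrom == "X":
                    c_chrom = "1" if rng.random() < config.x_syntenic_chr1_fraction else "4"
                    lo, hi = _SYNTENIC_BLOCK
                    c_start = int(rng.integers(lo, hi - _GENE_LEN))
                    rec["x_syntenic"] = True
                else:
                    c_chrom = str(rng.choice(list(config.chicken_autosomes)))
                    c_start = int(rng.integers(1, _CHICKEN_CHROM_LEN - _GENE_LEN))
                rec["chicken_chromosome"] = c_chrom
                rec["chicken_start"] = c_start
                rec["chicken_end"] = c_start + _GENE_LEN - 1
            records.append(rec)
    ann = pd.DataFrame.from_records(records).set_index("gene_id")
    ann["chicken_start"] = ann["chicken_start"].astype("Int64")
    ann["chicken_end"] = ann["chicken_end"].astype("Int64")
    truth = SyntheticTruth(true_ratio=dict(config.true_ratio),
                           hk_probability=dict(config.hk_probability))
    return ann, truth


def sample_stratum(
    means: np.ndarray,
    ploidy: np.ndarray,
    noise_a: float,
    noise_b_gene: np.ndarray,
    n_cells: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a genes x cells block: sum of `ploidy` independent Gamma alleles.

    ``noise_b_gene`` is the extrinsic CV^2 floor each gene would have at
    diploidy; per-allele variance is set so that total CV^2 =
    noise_a/mean + 2 * noise_b_gene / ploidy. Zero-mean genes yield zeros;
    zero-variance genes yield their mean exactly.
    """
    means = np.asarray(means, dtype=float)
    ploidy = np.asarray(ploidy)
    n_genes = means.size
    out = np.zeros((n_genes, n_cells))
    for p in np.unique(ploidy):
        if p == 0:
            continue
        sel = (ploidy == p) & (means > 0)
        if not sel.any():
            continue
        mu_allele = means[sel] / p                       # per-allele mean
        var_allele = noise_a * mu_allele + 2.0 * noise_b_gene[sel] * mu_allele**2
        block = np.zeros((int(sel.sum()), n_cells))
        deterministic = var_allele == 0
        if deterministic.any():
            block[deterministic, :] = (mu_allele[deterministic] * p)[:, None]
        stoch = ~deterministic
        if stoch.any():
            shape = (mu_allele[stoch] ** 2 / var_allele[stoch])[:, None]
            scale = (var_allele[stoch] / mu_allele[stoch])[:, None]
            total = np.zeros((int(stoch.sum()), n_cells))
            for _ in range(int(p)):
                total += rng.gamma(shape, scale, size=total.shape)
            block[stoch, :] = total
        out[sel, :] = block
    return out


def generate_expression(
    config: SyntheticConfig, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate the RPKM matrix and cell metadata for every configured stratum."""
    rng = _rng_for(config, 1)
    genes = annotation.index
    chrom = annotation["chromosome"]
    is_x = (chrom == "X").to_numpy()
    is_y = (chrom == "Y").to_numpy()
    is_hk = annotation["housekeeping"].to_numpy()

    base = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=len(genes))
    noise_b_gene = np.where(is_hk, config.noise_b * config.hk_noise_factor, config.noise_b)

    ploidy_by_sex = {}
    for sex in ("male", "female"):
        p = np.full(len(genes), 2, dtype=int)
        if sex == "male":
            p[is_x] = 1
            p[is_y] = 1
        else:
            p[is_y] = 0
        ploidy_by_sex[sex] = p

    columns: list[str] = []
    blocks: list[np.ndarray] = []
    meta_rows: list[dict] = []
    cell_sex: dict[str, str] = {}
    embryo_counter: dict[tuple[str, str], int] = {}

    for day, lineage, sex in config.strata:
        key = (day, sex)
        if key not in config.true_ratio:
            raise ValueError(f"true_ratio has no entry for (day={day}, sex={sex})")
        r = float(config.true_ratio[key])
        n_cells = int(config.n_cells_per_stratum)
        means = base.copy()
        means[is_x] *= r
        means[is_y] = config.y_male_mean if sex == "male" else 0.0
        block = sample_stratum(means, ploidy_by_sex[sex], config.noise_a,
                               noise_b_gene, n_cells, rng)
        blocks.append(block)
        for j in range(n_cells):
            cid = f"{day}_{lineage}_{sex}_c{j:03d}"
            columns.append(cid)
            count = embryo_counter.get(key, 0)
            embryo_counter[key] = count + 1
            emb = f"{day}_{sex}_emb{count // config.embryo_size:03d}"
            meta_rows.append({"cell_id": cid, "embryo_id": emb,
                              "day": day, "lineage": lineage})
            cell_sex[cid] = sex

    matrix = pd.DataFrame(np.concatenate(blocks, axis=1), index=genes, columns=columns)
    matrix.index.name = "gene_id"
    metadata = pd.DataFrame(meta_rows)
    truth = SyntheticTruth(
        true_ratio=dict(config.true_ratio),
        base_means=pd.Series(base, index=genes, name="base_mean"),
        cell_sex=pd.Series(cell_sex, name="sex"),
        ploidy=pd.DataFrame(ploidy_by_sex, index=genes),
        hk_probability=dict(config.hk_probability),
    )
    return matrix, metadata, truth


def simulate_to_dir(config: SyntheticConfig, outdir: str | Path) -> SyntheticTruth:
    """Write the three analysis inputs plus the ground-truth table to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, _ = generate_annotation(config)
    matrix, metadata, truth = generate_expression(config, annotation)
    write_gene_annotation(annotation, outdir / "genes.tsv")
    write_expression_matrix(matrix, outdir / "expression.tsv")
    write_cell_metadata(metadata, outdir / "cells.tsv")
    truth.write(outdir / "truth.tsv")
    return truth


def recovery_config(
    true_ratio: float,
    n_x: int = 2000,
    n_a: int = 10000,
    n_cells: int = 100,
    seed: int = 0,
    sex: str = "male",
    lognormal_sigma: float = 1.5,
) -> SyntheticConfig:
    """A single-stratum config for estimator-recovery experiments.

    ``n_a`` autosomal genes are spread over chromosomes 1-22; every gene
    carries an ortholog flag so gene counts are exact rather than binomial.
    """
    per_autosome = {str(i): n_a // 22 + (1 if i <= n_a % 22 else 0)
                    for i in range(1, 23)}
    counts = dict(per_autosome)
    counts["X"] = n_x
    counts["Y"] = 10
    day = "E5"
    return SyntheticConfig(
        n_genes_per_chromosome=counts,
        strata=[(day, "TE", sex)],
        n_cells_per_stratum=n_cells,
        lognormal_sigma=lognormal_sigma,
        ortholog_probability=1.0,
        true_ratio={(day, sex): true_ratio},
        seed=seed,
    )
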