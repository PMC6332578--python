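"""Full-analysis orchestration: every stratum, threshold and DM window.

``run_full_analysis`` reads the three input tables, calls cell sex from
Y-linked expression, forms (day, lineage, sex) strata and produces:

* population-level X:AA ratios (matched-fraction and common-threshold
  estimators) with bootstrap CIs and Mann-Whitney p-values,
* per-cell ratio summaries and per-autosome ratios,
* CV-ratio and DM-difference noise comparisons (X vs autosomal, X vs
  housekeeping, autosomal housekeeping vs other autosomal) per DM window,
* the housekeeping-depletion chi-squared suite (once per run),
* a gene-count table of genes passing each threshold per stratum.

The gene universe for the noise statistics is the union of the matched
selected sets at the same threshold, so expression-level composition matches
the ratio analysis. All randomness flows from the config seed; every output
TSV starts with a comment line recording the seed and a hash of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cells, enrichment, io, noise, ratio
from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    expression_path: str
    annotation_path: str
    cells_path: str
    thresholds: tuple[float, ...] = (10.0,)
    dm_windows: tuple[int, ...] = (20,)
    n_boot: int = 1000
    ci_level: float = 0.90
    y_threshold: float = 1.0
    embryo_vote: bool = True
    yates: bool = True
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")

    def config_hash(self) -> str:
        # outdir does not affect results, so two runs into different
        # directories still stamp the same hash
        doc = dataclasses.asdict(self)
        doc.pop("outdir")
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _check_consistency(matrix, annotation, metadata) -> tuple[pd.DataFrame, pd.DataFrame]:
    cell_overlap = matrix.columns.intersection(metadata["cell_id"])
    if len(cell_overlap) == 0:
        raise ValidationError("expression matrix and cell metadata share no cell ids")
    gene_overlap = matrix.index.intersection(annotation.index)
    if len(gene_overlap) == 0:
        raise ValidationError("expression matrix and annotation share no gene ids")
    if len(cell_overlap) < len(matrix.columns) or len(cell_overlap) < len(metadata):
        logger.warning(
            "cell ids only partially overlap (%d shared of %d matrix / %d metadata); "
            "restricting to the intersection",
            len(cell_overlap), len(matrix.columns), len(metadata),
        )
    if len(gene_overlap) < len(matrix.index):
        logger.warning("%d matrix gene(s) lack annotation and are dropped",
                       len(matrix.index) - len(gene_overlap))
    matrix = matrix.loc[gene_overlap, cell_overlap]
    metadata = metadata[metadata["cell_id"].isin(cell_overlap)].reset_index(drop=True)
    return matrix, metadata


def _ratio_rows(matrix, group, annotation, threshold, cfg, rng) -> list[dict]:
    rows = []
    base = {"day": group.day, "lineage": group.lineage, "sex": group.sex,
            "n_cells": group.n_cells, "threshold": threshold}
    for estimator, fn in (
        ("matched", ratio.xaa_ratio_population),
        ("common_threshold", ratio.xaa_ratio_common_threshold),
    ):
        try:
            est = fn(matrix, group, annotation, threshold,
                     n_boot=cfg.n_boot, level=cfg.ci_level, seed=rng)
        except DegenerateInputError as exc:
            logger.warning("stratum %s, %s estimator skipped: %s",
                           group.label, estimator, exc)
            continue
        rows.append({**base, "estimator": estimator, "ratio": est.point,
                     "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "mwu_p": est.mwu_p, "significant": est.mwu_p < 0.05,
                     "n_x": est.n_x, "n_a": est.n_a})
    return rows


def _noise_rows(matrix, group, annotation, threshold, cfg, rng) -> list[dict]:
    if group.n_cells < 2:
        logger.warning("stratum %s has < 2 cells; noise statistics skipped", group.label)
        return []
    means = matrix[list(group.cell_ids)].mean(axis=1)
    try:
        sets = ratio.select_matched_gene_sets(means, annotation, threshold)
    except DegenerateInputError as exc:
        logger.warning("stratum %s noise skipped: %s", group.label, exc)
        return []
    pool = list(dict.fromkeys(list(sets.selected_x) + list(sets.selected_a)))
    table = noise.gene_noise_table(matrix, group.cell_ids, pool)

    hk = annotation["housekeeping"]
    x_ids = table.index.intersection(list(sets.selected_x))
    a_ids = table.index.intersection(list(sets.selected_a))
    hk_mask = hk.reindex(a_ids, fill_value=False).to_numpy()
    hk_a_ids = a_ids[hk_mask]
    nonhk_a_ids = a_ids[~hk_mask]

    rows = []
    base = {"day": group.day, "lineage": group.lineage, "sex": group.sex,
            "n_cells": group.n_cells, "threshold": threshold}

    def _append(comp, k):
        rows.append({**base, "window_k": k, "kind": comp.kind,
                     "set_a": comp.set_a, "set_b": comp.set_b,
                     "point": comp.point, "ci_low": comp.ci_low,
                     "ci_high": comp.ci_high, "mwu_p": comp.mwu_p,
                     "significant": comp.mwu_p < 0.05,
                     "n_a": comp.n_a, "n_b": comp.n_b})

    try:
        comp = noise.cv_ratio(table.loc[x_ids], table.loc[a_ids],
                              n_boot=cfg.n_boot, level=cfg.ci_level, seed=rng)
        _append(comp, 0)
    except DegenerateInputError as exc:
        logger.warning("stratum %s cv_ratio skipped: %s", group.label, exc)

    for k in cfg.dm_windows:
        try:
            with_dm = noise.compute_dm(table, k=k)
        except DegenerateInputError as exc:
            logger.warning("stratum %s DM(k=%d) skipped: %s", group.label, k, exc)
            continue
        pairs = [
            (x_ids, a_ids, "X", "autosomal"),
            (x_ids, hk_a_ids, "X", "housekeeping"),
            (hk_a_ids, nonhk_a_ids, "autosomal_housekeeping", "autosomal"),
        ]
        for ids_a, ids_b, label_a, label_b in pairs:
            if len(ids_a) == 0 or len(ids_b) == 0:
                logger.info("stratum %s: empty set for %s vs %s", group.label,
                            label_a, label_b)
                continue
            comp = noise.dm_difference(
                with_dm.loc[ids_a], with_dm.loc[ids_b],
                n_boot=cfg.n_boot, level=cfg.ci_level, seed=rng,
                set_a=label_a, set_b=label_b,
            )
            _append(comp, k)
    return rows


def run_full_analysis(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the complete analysis; returns (and optionally writes) result tables."""
    matrix = io.read_expression_matrix(cfg.expression_path)
    annotation = io.read_gene_annotation(cfg.annotation_path)
    metadata = io.read_cell_metadata(cfg.cells_path)
    matrix, metadata = _check_consistency(matrix, annotation, metadata)

    sex = cells.call_cell_sex(matrix, annotation, metadata,
                              y_threshold=cfg.y_threshold,
                              embryo_vote=cfg.embryo_vote)
    metadata = metadata.assign(sex=sex.reindex(metadata["cell_id"]).to_numpy())
    groups = cells.group_cells(metadata)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(2,)))
    ratio_rows, per_cell_rows, per_auto_rows, noise_rows, count_rows = [], [], [], [], []
    for group in groups:
        for threshold in cfg.thresholds:
            ratio_rows.extend(_ratio_rows(matrix, group, annotation, threshold, cfg, rng))
            try:
                summary = ratio.xaa_ratio_per_cell(matrix, group, annotation, threshold)
                per_cell_rows.append({
                    "day": group.day, "lineage": group.lineage, "sex": group.sex,
                    "threshold": threshold, "n_cells": group.n_cells,
                    "n_skipped": summary.n_skipped, "median": summary.median,
                    "minimum": summary.minimum, "maximum": summary.maximum,
                })
            except DegenerateInputError as exc:
                logger.warning("stratum %s per-cell ratio skipped: %s", group.label, exc)
            per_auto = ratio.xaa_ratio_per_autosome(
                matrix, group, annotation, threshold,
                n_boot=cfg.n_boot, level=cfg.ci_level, seed=rng)
            for chrom, est in per_auto.items():
                per_auto_rows.append({
                    "day": group.day, "lineage": group.lineage, "sex": group.sex,
                    "threshold": threshold, "autosome": chrom, "ratio": est.point,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "mwu_p": est.mwu_p, "n_x": est.n_x, "n_a": est.n_a,
                })
            noise_rows.extend(_noise_rows(matrix, group, annotation, threshold, cfg, rng))

            means = matrix[list(group.cell_ids)].mean(axis=1)
            ann = annotation.loc[annotation.index.intersection(means.index)]
            ann = ann.loc[ann["one2one_chicken"]]
            x_ids = ann.index[ann["chromosome"] == "X"]
            a_ids = ann.index[ann["chromosome"].isin(io.AUTOSOMES)]
            count_rows.append({
                "day": group.day, "lineage": group.lineage, "sex": group.sex,
                "threshold": threshold,
                "n_x_passing": int((means.loc[x_ids] >= threshold).sum()),
                "n_a_passing": int((means.loc[a_ids] >= threshold).sum()),
                "n_x_total": len(x_ids), "n_a_total": len(a_ids),
            })

    enrich_rows = [dataclasses.asdict(res)
                   for res in enrichment.housekeeping_depletion_suite(
                       annotation, yates=cfg.yates)]

    results = {
        "ratios": pd.DataFrame(ratio_rows),
        "per_cell_ratios": pd.DataFrame(per_cell_rows),
        "per_autosome_ratios": pd.DataFrame(per_auto_rows),
        "noise_comparisons": pd.DataFrame(noise_rows),
        "enrichment": pd.DataFrame(enrich_rows),
        "gene_counts": pd.DataFrame(count_rows),
        "cell_sex": pd.DataFrame({"cell_id": metadata["cell_id"],
                                  "sex": metadata["sex"]}),
    }
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = (f"# xdosage run: seed={cfg.seed} config_hash={cfg.config_hash()} "
                  f"ci=linear-interpolated percentile bootstrap\n")
        for name, df in results.items():
            path = outdir / f"{name}.tsv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, sep="\t", index=False)
    return results
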