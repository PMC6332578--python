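"""Sex calling from Y-linked expression and (day, lineage, sex) stratification.

A cell is called male when the summed RPKM of Y-linked genes exceeds a
threshold (default 1.0 RPKM); the sum is robust to dropout of any single Y
gene. Because all cells of one embryo share a karyotype, per-cell calls are
by default overridden by the embryo's majority call (ties give "unknown").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellGroup:
    """An analysis stratum: all cells sharing (day, lineage, sex)."""

    day: str
    lineage: str
    sex: str
    cell_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.cell_ids:
            raise ValueError("CellGroup requires at least one member cell")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def label(self) -> str:
        return f"{self.day}/{self.lineage}/{self.sex}"


def call_cell_sex(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    y_threshold: float = 1.0,
    embryo_vote: bool = True,
) -> pd.Series:
    """Call each cell's sex from summed Y-linked expression.

    Parameters
    ----------
    matrix
        Genes x cells RPKM matrix.
    annotation
        Gene annotation indexed by gene_id, with a ``chromosome`` column.
    metadata
        Per-cell table with ``cell_id`` and ``embryo_id``; required when
        ``embryo_vote`` is on.
    y_threshold
        A cell is male iff its summed Y-linked RPKM is strictly above this.
    embryo_vote
        Reassign every cell of an embryo the embryo's majority call; an
        exact tie yields "unknown" for the whole embryo.

    Returns
    -------
    pandas.Series mapping cell id to "male"/"female"/"unknown".
    """
    y_genes = annotation.index[annotation["chromosome"] == "Y"].intersection(matrix.index)
    if len(y_genes) == 0:
        raise DegenerateInputError(
            "no Y-linked genes shared between annotation and matrix; sex cannot be called"
        )
    score = matrix.loc[y_genes].sum(axis=0)
    sex = pd.Series(
        pd.Series("female", index=matrix.columns).where(score <= y_threshold, "male"),
        name="sex",
    )

    if embryo_vote:
        if metadata is None:
            raise ValueError("embryo_vote requires cell metadata with embryo_id")
        embryo = metadata.set_index("cell_id")["embryo_id"].reindex(sex.index)
        if embryo.isna().any():
            missing = sex.index[embryo.isna()][0]
            raise ValueError(f"cell {missing!r} has no metadata row; cannot run embryo vote")
        for emb, cells in sex.groupby(embryo):
            n_male = int((cells == "male").sum())
            n_female = int((cells == "female").sum())
            if n_male > n_female:
                call = "male"
            elif n_female > n_male:
                call = "female"
            else:
                call = "unknown"
                logger.warning("embryo %s: tied sex vote (%d/%d), calling unknown",
                               emb, n_male, n_female)
            sex.loc[cells.index] = call
    return sex


def group_cells(metadata: pd.DataFrame) -> list[CellGroup]:
    """Partition cells into (day, lineage, sex) strata.

    Cells with sex "unknown" are excluded and counted in the log. Every cell
    with a known sex lands in exactly one group.
    """
    known = metadata[metadata["sex"] != "unknown"]
    n_dropped = len(metadata) - len(known)
    if n_dropped:
        logger.warning("%d cell(s) with unknown sex excluded from stratification", n_dropped)
    groups: list[CellGroup] = []
    for (day, lineage, sex), sub in known.groupby(["day", "lineage", "sex"], sort=True):
        groups.append(CellGroup(day=day, lineage=lineage, sex=sex,
                                cell_ids=tuple(sub["cell_id"])))
    return groups
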