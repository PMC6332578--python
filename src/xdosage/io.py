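"""Readers and writers for the three input tables, plus gene-level filters.

All files are UTF-8, tab-separated, with a mandatory header row and decimal
points (never commas). Coordinates are 1-based inclusive, Ensembl style; any
BED-style half-open input must be converted by the caller.

The expression matrix is held as a pandas DataFrame of non-negative RPKM
values with genes as rows and cells as columns. The gene annotation is a
DataFrame indexed by ``gene_id`` with the columns listed in
:data:`ANNOTATION_COLUMNS`; the cell metadata is a DataFrame with one row per
cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MatrixParseError, ValidationError

logger = logging.getLogger(__name__)

#: Chromosome labels recognised for human genes; anything else becomes "other".
VALID_CHROMOSOMES = frozenset([str(i) for i in range(1, 23)] + ["X", "Y", "MT"])

#: The autosomal labels used in every X-vs-autosome contrast. Genes on
#: "MT"/"other" are kept in files but never enter these statistics.
AUTOSOMES = tuple(str(i) for i in range(1, 23))

ANNOTATION_COLUMNS = (
    "gene_id",
    "chromosome",
    "start",
    "end",
    "housekeeping",
    "one2one_chicken",
    "chicken_chromosome",
    "chicken_start",
    "chicken_end",
    "x_syntenic",
)

CELL_METADATA_COLUMNS = ("cell_id", "embryo_id", "day", "lineage")

DAYS = ("E3", "E4", "E5", "E6", "E7")
LINEAGES = ("TE", "PE", "EPI", "prelineage")
SEXES = ("male", "female", "unknown")

_TRUE_STRINGS = {"true", "1", "t", "yes"}
_FALSE_STRINGS = {"false", "0", "f", "no"}


def _parse_bool(value, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean in column {column!r}")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a genes x cells RPKM table.

    First row holds cell ids, first column gene ids. Every remaining field
    must parse as a non-negative finite real. Malformed or out-of-domain
    fields raise :class:`MatrixParseError` naming the offending gene/cell;
    duplicated ids raise :class:`ValidationError`. Nothing is dropped
    silently.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for cell in header:
        if cell in seen:
            raise ValidationError(f"duplicate cell id {cell!r} in {path}")
        seen.add(cell)

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.columns = header
    raw.index = raw.index.astype(str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r} in {path}")

    def _parse_column(col: pd.Series) -> pd.Series:
        try:
            # numpy's str->float conversion is round-trip exact
            return col.to_numpy().astype(float)
        except ValueError:
            for gene, value in col.items():
                try:
                    float(value)
                except ValueError:
                    raise MatrixParseError(
                        f"non-numeric value {value!r} at gene {gene!r}, "
                        f"cell {col.name!r} in {path}"
                    ) from None
            raise

    matrix = raw.apply(_parse_column)
    values = matrix.to_numpy()
    bad = ~np.isfinite(values) | (values < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise MatrixParseError(
            f"value {values[i, j]!r} at gene {matrix.index[i]!r}, cell "
            f"{matrix.columns[j]!r} in {path} is negative or non-finite"
        )
    matrix.index.name = "gene_id"
    return matrix


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a matrix in the format :func:`read_expression_matrix` accepts."""
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read the per-gene annotation table.

    Returns a DataFrame indexed by ``gene_id`` with typed columns. Unknown
    chromosome labels are mapped to ``"other"`` with a logged warning. The
    chicken columns (``chicken_chromosome``, ``chicken_start``,
    ``chicken_end``) must be present exactly for genes flagged
    ``one2one_chicken``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation file {path} lacks mandatory column(s): {missing}")

    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene id {dup!r} in annotation {path}")

    chrom = df["chromosome"].astype(str).str.strip()
    unknown = ~chrom.isin(VALID_CHROMOSOMES)
    if unknown.any():
        labels = sorted(chrom[unknown].unique())
        logger.warning(
            "%d gene(s) on unrecognised chromosome label(s) %s mapped to 'other'",
            int(unknown.sum()), labels,
        )
        chrom = chrom.where(~unknown, "other")

    out = pd.DataFrame(index=pd.Index(df["gene_id"].astype(str), name="gene_id"))
    out["chromosome"] = chrom.to_numpy()
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 1).any():
            bad = df.loc[vals.isna() | (vals < 1), "gene_id"].iloc[0]
            raise ValidationError(f"gene {bad!r}: column {col!r} must be a positive integer")
        out[col] = vals.astype(np.int64).to_numpy()
    if (out["start"] > out["end"]).any():
        bad = out.index[out["start"] > out["end"]][0]
        raise ValidationError(f"gene {bad!r}: start exceeds end")

    for col in ("housekeeping", "one2one_chicken", "x_syntenic"):
        out[col] = np.array([_parse_bool(v, col) for v in df[col]], dtype=bool)

    cchrom = df["chicken_chromosome"].astype(str).str.strip().replace({"": None, "NA": None})
    out["chicken_chromosome"] = cchrom.to_numpy()
    for col in ("chicken_start", "chicken_end"):
        vals = pd.to_numeric(df[col].replace({"": None, "NA": None}), errors="coerce")
        out[col] = vals.astype("Int64").to_numpy()

    ortho = out["one2one_chicken"]
    chicken_present = (
        out["chicken_chromosome"].notna()
        & out["chicken_start"].notna()
        & out["chicken_end"].notna()
    )
    breach = ortho != chicken_present
    if breach.any():
        bad = out.index[breach][0]
        raise ValidationError(
            f"gene {bad!r}: chicken ortholog fields must be present exactly when "
            "one2one_chicken is true"
        )
    return out


def write_gene_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.reset_index()
    for col in ("housekeeping", "one2one_chicken", "x_syntenic"):
        out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Cell metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellRecord:
    """One sequenced cell: embryo of origin, embryonic day and lineage."""

    cell_id: str
    embryo_id: str
    day: str
    lineage: str
    sex: str = "unknown"


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-cell metadata table (cell_id, embryo_id, day, lineage).

    An optional ``sex`` column is honoured; otherwise all cells start as
    ``"unknown"`` and must be assigned by the sex caller.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CELL_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cell metadata {path} lacks mandatory column(s): {missing}")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValidationError(f"duplicate cell id {dup!r} in {path}")
    bad_day = ~df["day"].isin(DAYS)
    if bad_day.any():
        raise ValidationError(
            f"unknown day label {df.loc[bad_day, 'day'].iloc[0]!r}; expected one of {DAYS}"
        )
    bad_lin = ~df["lineage"].isin(LINEAGES)
    if bad_lin.any():
        raise ValidationError(
            f"unknown lineage {df.loc[bad_lin, 'lineage'].iloc[0]!r}; expected one of {LINEAGES}"
        )
    out = df[list(CELL_METADATA_COLUMNS)].copy()
    if "sex" in df.columns:
        bad_sex = ~df["sex"].isin(SEXES)
        if bad_sex.any():
            raise ValidationError(
                f"unknown sex {df.loc[bad_sex, 'sex'].iloc[0]!r}; expected one of {SEXES}"
            )
        out["sex"] = df["sex"]
    else:
        out["sex"] = "unknown"
    return out


def write_cell_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene-level filters
# ---------------------------------------------------------------------------

def filter_one2one_orthologs(annotation: pd.DataFrame) -> set[str]:
    """Gene ids with a one-to-one chicken ortholog — the analysis universe."""
    return set(annotation.index[annotation["one2one_chicken"]])


def filter_expressed_genes(
    matrix: pd.DataFrame, min_cells: int = 5, min_rpkm: float = 10.0
) -> set[str]:
    """Genes expressed at >= ``min_rpkm`` RPKM in >= ``min_cells`` cells."""
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if min_rpkm < 0:
        raise ValueError("min_rpkm must be >= 0")
    n_passing = (matrix.to_numpy() >= min_rpkm).sum(axis=1)
    return set(matrix.index[n_passing >= min_cells])
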