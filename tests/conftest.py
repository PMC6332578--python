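"""Shared fixtures: tiny hand-built annotation/expression tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

_ANN_DEFAULTS = {
    "chromosome": "1",
    "start": 100,
    "end": 200,
    "housekeeping": False,
    "one2one_chicken": True,
    "chicken_chromosome": "2",
    "chicken_start": 100,
    "chicken_end": 200,
    "x_syntenic": False,
}


def make_annotation(genes: dict[str, dict]) -> pd.DataFrame:
    """Build an annotation frame from {gene_id: field overrides}.

    Genes default to autosomal one-to-one orthologs mapped to chicken chr2.
    Setting ``one2one_chicken`` to False clears the chicken fields.
    """
    rows = []
    for gid, overrides in genes.items():
        rec = dict(_ANN_DEFAULTS, gene_id=gid, **overrides)
        if not rec["one2one_chicken"]:
            rec["chicken_chromosome"] = None
            rec["chicken_start"] = pd.NA
            rec["chicken_end"] = pd.NA
        rows.append(rec)
    df = pd.DataFrame(rows).set_index("gene_id")
    df["chicken_start"] = df["chicken_start"].astype("Int64")
    df["chicken_end"] = df["chicken_end"].astype("Int64")
    return df


def make_matrix(values: dict[str, list[float]], cells: list[str]) -> pd.DataFrame:
    """Genes x cells matrix from {gene_id: per-cell values}."""
    df = pd.DataFrame.from_dict(values, orient="index", columns=cells, dtype=float)
    df.index.name = "gene_id"
    return df


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
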