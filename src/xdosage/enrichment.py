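"""Housekeeping-gene depletion tests on the X and its chicken proto-chromosomes.

The human X evolved from ancestral autosomes whose descendants in chicken are
chromosomes 1 and 4 (which carry blocks syntenic to the human X). If
dosage-sensitive genes avoid X linkage, housekeeping genes should be
under-represented both on the present-day X and on those proto-X
chromosomes. Each test is a 2x2 chi-squared contingency comparison of
housekeeping vs non-housekeeping counts between a focal gene set and a
reference set, restricted throughout to genes with one-to-one chicken
orthologs. Yates' continuity correction is applied by default (switchable).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError
from .io import AUTOSOMES

#: Chicken sex chromosomes, never counted among "other chicken autosomes".
CHICKEN_SEX_CHROMOSOMES = ("Z", "W")


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 chi-squared test: (a, c) housekeeping and (b, d) other genes in
    the focal and reference sets respectively."""

    label: str
    a: int
    b: int
    c: int
    d: int
    chi2: float
    p: float
    yates: bool

    @property
    def focal_fraction(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def reference_fraction(self) -> float:
        return self.c / (self.c + self.d)


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = True,
             label: str = "") -> ContingencyResult:
    """Pearson chi-squared test of a 2x2 table, optional Yates correction.

    chi2 = N (|ad - bc| - correction)^2 / (R1 R2 C1 C2) with correction = N/2
    when ``yates`` (clamped so chi2 never goes negative), df = 1.
    """
    counts = (a, b, c, d)
    if any(x < 0 for x in counts):
        raise ValidationError("contingency counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateInputError("chi-squared undefined with a zero marginal")
    num = abs(a * d - b * c) - (n / 2.0 if yates else 0.0)
    num = max(num, 0.0)
    chi2 = n * num * num / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return ContingencyResult(label=label, a=a, b=b, c=c, d=d,
                             chi2=float(chi2), p=p, yates=yates)


def syntenic_span_subset(annotation: pd.DataFrame, chicken_chrom: str) -> set[str]:
    """Ortholog genes on a chicken chromosome within its X-syntenic span.

    The span runs from the first to the last one-to-one ortholog flagged as
    lying in a block syntenic to the human X; every ortholog gene on that
    chromosome whose chicken interval falls inside the span (inclusive) is
    returned, flagged or not.
    """
    ann = annotation[annotation["one2one_chicken"]]
    on_chrom = ann[ann["chicken_chromosome"] == chicken_chrom]
    flagged = on_chrom[on_chrom["x_syntenic"]]
    if len(flagged) == 0:
        raise DegenerateInputError(
            f"no X-syntenic ortholog genes on chicken chromosome {chicken_chrom}"
        )
    span_lo = int(flagged["chicken_start"].min())
    span_hi = int(flagged["chicken_end"].max())
    inside = (on_chrom["chicken_start"] >= span_lo) & (on_chrom["chicken_end"] <= span_hi)
    return set(on_chrom.index[inside])


def _counts(ann: pd.DataFrame, focal_ids, reference_ids) -> tuple[int, int, int, int]:
    hk = ann["housekeeping"]
    focal = ann.index.isin(list(focal_ids))
    ref = ann.index.isin(list(reference_ids))
    a = int((hk & focal).sum())
    b = int((~hk & focal).sum())
    c = int((hk & ref).sum())
    d = int((~hk & ref).sum())
    return a, b, c, d


def housekeeping_depletion_suite(
    annotation: pd.DataFrame, yates: bool = True
) -> list[ContingencyResult]:
    """The five depletion tests: human X, chicken chr1/chr4 (complete), and
    the X-syntenic spans of chicken chr1/chr4, each against the remaining
    autosomes, restricted to one-to-one ortholog genes. The focal chromosome
    is always excluded from its reference set.
    """
    ann = annotation[annotation["one2one_chicken"]]
    results: list[ContingencyResult] = []

    human_x = set(ann.index[ann["chromosome"] == "X"])
    human_auto = set(ann.index[ann["chromosome"].isin(AUTOSOMES)])
    results.append(chi2_2x2(*_counts(ann, human_x, human_auto), yates=yates,
                            label="human_X_vs_autosomes"))

    cchrom = ann["chicken_chromosome"]
    chicken_autosomal = ann.index[
        cchrom.notna() & ~cchrom.isin(CHICKEN_SEX_CHROMOSOMES) & (cchrom != "other")
    ]
    for chrom in ("1", "4"):
        focal = set(ann.index[cchrom == chrom])
        ref = set(chicken_autosomal) - focal
        results.append(chi2_2x2(*_counts(ann, focal, ref), yates=yates,
                                label=f"chicken_chr{chrom}_complete"))
    for chrom in ("1", "4"):
        focal = syntenic_span_subset(annotation, chrom)
        ref = set(chicken_autosomal) - set(ann.index[cchrom == chrom])
        results.append(chi2_2x2(*_counts(ann, focal, ref), yates=yates,
                                label=f"chicken_chr{chrom}_syntenic_span"))
    return results
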