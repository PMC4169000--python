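"""Downstream analyses: class/pattern concordance, correlations, enrichment,
and qPCR-vs-count fold-change comparison.

The screen's four DGE classes predict where and when a transcript is
expressed in the embryo: class 1 transcripts tend to show Oral (O) in situ
patterns, class 2 Ingressing/Endodermal (IE), class 3 Aboral (A) and class 4
Delayed (D) or mixed D/A patterns.  :func:`class_pattern_table` tallies that
concordance.  :func:`taxon_enrichment` asks whether taxon-restricted genes
are over-represented in a group of classes, using an exact 2x2 test;
:func:`fisher_exact_2x2` computes that test by exact integer enumeration of
the hypergeometric distribution (two-sided p = sum of outcome probabilities
not exceeding the observed table's).  Fold changes measured by quantitative
PCR (expression level ``N = 2**-Ct``, reference-gene normalised, i.e. the
2^-ddCt method) and by mapped-read counts are put on a common ratio scale by
:func:`normalized_fold_change`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

__all__ = [
    "PATTERNS",
    "AnnotatedTranscript",
    "ContingencyTable2x2",
    "FisherResult",
    "class_pattern_table",
    "pearson_correlation",
    "fisher_exact_2x2",
    "taxon_enrichment",
    "qpcr_expression",
    "normalized_fold_change",
]

#: in situ expression pattern vocabulary: Oral, Oral + later endoderm,
#: Ingressing/Endodermal, Aboral, Delayed, mixed Delayed/Aboral.
PATTERNS = ("O", "O_endo", "IE", "A", "D", "D_A")

#: default grouping for concordance counting: O_endo counts as O-type,
#: D and D_A stay distinct.
DEFAULT_PATTERN_GROUPING = {
    "O": "O",
    "O_endo": "O",
    "IE": "IE",
    "A": "A",
    "D": "D",
    "D_A": "D_A",
}


@dataclass(frozen=True)
class AnnotatedTranscript:
    """One characterised transcript: screen z, class, pattern, annotations."""

    name: str
    z_wnt3: float
    dge_class: int
    pattern: str
    restricted_flag: bool = False
    orf_complete_flag: bool = True

    def __post_init__(self):
        if self.dge_class not in (1, 2, 3, 4):
            raise ValueError(f"{self.name}: DGE class must be 1-4")
        if self.pattern not in PATTERNS:
            raise ValueError(f"{self.name}: unknown expression pattern {self.pattern!r}")


def class_pattern_table(
    records, pattern_grouping: dict[str, str] | None = None
) -> pd.DataFrame:
    """Count transcripts per (DGE class, pattern group).

    Returns a class-by-group table with a ``total`` column; cell sums equal
    the number of records.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    grouping = DEFAULT_PATTERN_GROUPING if pattern_grouping is None else pattern_grouping
    groups = sorted(set(grouping.values()), key=list(grouping.values()).index)
    table = pd.DataFrame(0, index=[1, 2, 3, 4], columns=groups, dtype=int)
    table.index.name = "dge_class"
    for rec in records:
        if rec.pattern not in grouping:
            raise ValueError(f"{rec.name}: pattern {rec.pattern!r} not in grouping")
        table.loc[rec.dge_class, grouping[rec.pattern]] += 1
    table["total"] = table.sum(axis=1)
    return table


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D sequences of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant sequence")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 counts; rows are groups, columns the property (yes/no)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("cells must be non-negative integers")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float  # inf when bc = 0 and ad > 0, nan for 0/0
    p_value: float


def fisher_exact_2x2(t: ContingencyTable2x2) -> FisherResult:
    """Fisher's exact test by full hypergeometric enumeration.

    Conditions on both margins; the two-sided p-value sums the probabilities
    of every table (same margins) whose probability does not exceed the
    observed one.  All comparisons are done on exact integer weights
    ``C(r1, k) * C(r2, c1 - k)``, so ties are resolved exactly; the p-value
    is returned as a float of an exact rational.
    """
    a, b, c, d = int(t.a), int(t.b), int(t.c), int(t.d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if a * d == 0 and b * c == 0:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    p = Fraction(num, math.comb(n, c1))
    return FisherResult(odds_ratio=odds, p_value=float(p))


def taxon_enrichment(records, group_a: set[int], group_b: set[int]):
    """Compare the taxon-restricted proportion between two groups of classes.

    Only records with a complete predicted ORF enter the comparison (the
    restriction call needs the full coding sequence).  Returns
    ``(proportion_a, proportion_b, FisherResult)`` for the 2x2 table
    (restricted, not-restricted) x (group_a, group_b).
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b or group_a & group_b:
        raise ValueError("groups must be non-empty and disjoint")
    usable = [r for r in records if r.orf_complete_flag]
    in_a = [r for r in usable if r.dge_class in group_a]
    in_b = [r for r in usable if r.dge_class in group_b]
    if not in_a or not in_b:
        raise ValueError("a group is empty after the complete-ORF filter")
    ra = sum(r.restricted_flag for r in in_a)
    rb = sum(r.restricted_flag for r in in_b)
    table = ContingencyTable2x2(ra, len(in_a) - ra, rb, len(in_b) - rb)
    return ra / len(in_a), rb / len(in_b), fisher_exact_2x2(table)


def qpcr_expression(ct: float) -> float:
    """Expression level ``N = 2**-Ct`` from a qPCR cycle threshold."""
    ct = float(ct)
    if not math.isfinite(ct):
        raise ValueError("Ct must be finite")
    return 2.0 ** (-ct)


def normalized_fold_change(
    gene_experimental: float,
    gene_control: float,
    reference_experimental: float,
    reference_control: float,
    *,
    measure: str = "ct",
) -> float:
    """Reference-normalised fold change, experimental over control.

    With ``measure='ct'`` inputs are qPCR cycle thresholds and the result is
    ``2**-ddCt``; with ``measure='count'`` inputs are mapped-read counts and
    the result is ``(gene/ref)_exp / (gene/ref)_ctl``.  Both land on the same
    ratio scale for side-by-side comparison.
    """
    if measure == "ct":
        ddct = (gene_experimental - reference_experimental) - (
            gene_control - reference_control
        )
        return 2.0 ** (-ddct)
    if measure == "count":
        for name, v in (
            ("reference_experimental", reference_experimental),
            ("reference_control", reference_control),
            ("gene_control", gene_control),
        ):
            if v == 0:
                raise ValueError(f"{name} must be non-zero")
        return (gene_experimental / reference_experimental) / (
            gene_control / reference_control
        )
    raise ValueError("measure must be 'ct' or 'count'")
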