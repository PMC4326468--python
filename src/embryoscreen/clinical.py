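"""Cohort tables and clinical outcome statistics.

Aggregates per-embryo four-way classifications into an indication-stratified
cohort table, and compares clinical outcome rates between two treatment
groups with Pearson's chi-squared test on 2x2 contingency tables (no
continuity correction, 1 degree of freedom).

The four standard outcome measures and their denominator conventions:

* clinical pregnancy rate — pregnancies per embryo-transfer cycle
* ongoing pregnancy rate  — ongoing pregnancies per transfer cycle
* miscarriage rate        — miscarriages per clinical pregnancy
* implantation rate       — gestational sacs per embryo transferred
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InconsistentCountsError
from .karyotype import CLASSES

__all__ = [
    "OutcomeTable",
    "CohortSummary",
    "pearson_chi2_2x2",
    "build_outcome_tables",
    "aggregate_cohort",
    "OUTCOME_MEASURES",
]


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared on the 2x2 table [[a, b], [c, d]].

    Expected counts come from the row/column margins; no Yates continuity
    correction is applied; the p-value uses 1 df. Raises on a zero margin.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise InconsistentCountsError("counts must be nonnegative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise InconsistentCountsError("a zero row or column margin: test undefined")
    chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(chi2), float(p)


@dataclass(frozen=True)
class OutcomeTable:
    """One outcome measure compared between two groups."""

    label: str
    a: int  # successes, group 1
    b: int  # failures, group 1
    c: int  # successes, group 2
    d: int  # failures, group 2
    rate1: float  # percent
    rate2: float  # percent
    pooled_rate: float  # percent, both groups combined
    chi2: float | None
    p_value: float | None
    testable: bool = True


OUTCOME_MEASURES = (
    "clinical_pregnancy",
    "ongoing_pregnancy",
    "miscarriage",
    "implantation",
)

_LABELS = {
    "clinical_pregnancy": "Clinical pregnancy rate per ET",
    "ongoing_pregnancy": "Ongoing pregnancy rate",
    "miscarriage": "Miscarriage rate",
    "implantation": "Implantation rate",
}


def _one_table(label, num1, den1, num2, den2) -> OutcomeTable:
    if num1 > den1 or num2 > den2:
        raise InconsistentCountsError(f"{label}: numerator exceeds denominator")
    a, b = int(num1), int(den1 - num1)
    c, d = int(num2), int(den2 - num2)
    rate1 = 100.0 * a / den1 if den1 else 0.0
    rate2 = 100.0 * c / den2 if den2 else 0.0
    pooled = 100.0 * (a + c) / (den1 + den2) if den1 + den2 else 0.0
    try:
        chi2, p = pearson_chi2_2x2(a, b, c, d)
        return OutcomeTable(label, a, b, c, d, rate1, rate2, pooled, chi2, p, True)
    except InconsistentCountsError:
        return OutcomeTable(label, a, b, c, d, rate1, rate2, pooled, None, None, False)


def build_outcome_tables(group1: dict, group2: dict) -> list[OutcomeTable]:
    """Build the four outcome tables from per-group count dictionaries.

    Each group dict carries ``transfer_cycles``, ``clinical_pregnancies``,
    ``ongoing_pregnancies``, ``miscarriages``, ``embryos_transferred`` and
    ``implantations``. Denominators follow the standard conventions (see
    module docstring); the miscarriage denominator is the clinical
    pregnancies of the same group.
    """
    for g in (group1, group2):
        if g["miscarriages"] > g["clinical_pregnancies"]:
            raise InconsistentCountsError("more miscarriages than pregnancies")
    tables = []
    specs = {
        "clinical_pregnancy": ("clinical_pregnancies", "transfer_cycles"),
        "ongoing_pregnancy": ("ongoing_pregnancies", "transfer_cycles"),
        "miscarriage": ("miscarriages", "clinical_pregnancies"),
        "implantation": ("implantations", "embryos_transferred"),
    }
    for key in OUTCOME_MEASURES:
        num_k, den_k = specs[key]
        tables.append(
            _one_table(
                _LABELS[key], group1[num_k], group1[den_k], group2[num_k], group2[den_k]
            )
        )
    return tables


@dataclass(frozen=True)
class CohortSummary:
    """Classification x indication-stratum cross-tabulation."""

    counts: pd.DataFrame  # rows: CLASSES, columns: strata (+ 'Total')
    percentages: pd.DataFrame  # same shape, percent of stratum total

    @property
    def total_biopsied(self) -> int:
        return int(self.counts["Total"].sum())

    def overall_rate(self, classification: str) -> float:
        """Percent of all embryos in *classification*."""
        return float(self.percentages.loc[classification, "Total"])


def aggregate_cohort(results, strata) -> CohortSummary:
    """Cross-tabulate embryo classifications against indication strata.

    *results* is an iterable of objects with ``classification``; *strata*
    is a parallel iterable of stratum labels (e.g. "Robertsonian
    translocation", "AMA and/or RM"). Every embryo must carry a label.
    """
    results = list(results)
    strata = list(strata)
    if len(results) != len(strata):
        raise InconsistentCountsError("one stratum label required per embryo")
    if any(s is None or s == "" for s in strata):
        raise InconsistentCountsError("unlabeled embryo in cohort")
    cls = [r.classification for r in results]
    stratum_order = list(dict.fromkeys(strata))
    counts = pd.DataFrame(0, index=list(CLASSES), columns=stratum_order, dtype=int)
    for c, s in zip(cls, strata):
        counts.loc[c, s] += 1
    counts["Total"] = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / col_tot
    return CohortSummary(counts=counts, percentages=pct)
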