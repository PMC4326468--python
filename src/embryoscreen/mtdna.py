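"""Relative mtDNA copy-number comparison between embryo groups.

The per-embryo statistic is the depth ratio ChrM_depth / Mean_depth (see
:func:`embryoscreen.coverage.mito_stats`). Euploid embryos are compared
against all chromosomally abnormal embryos with a two-sided Mann-Whitney
U test: exact enumeration for small tie-free samples, otherwise the
normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError
from .karyotype import CLASS_EUPLOID

__all__ = ["MtDnaComparison", "mann_whitney", "compare_groups"]

#: largest per-group size for which the exact null distribution is used
EXACT_MAX_N = 8


@dataclass(frozen=True)
class MtDnaComparison:
    group_euploid: tuple[float, ...]
    group_abnormal: tuple[float, ...]
    U: float
    p_value: float
    direction: str  # "euploid greater" | "abnormal greater" | "no difference"


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; U is reported for group *a*.

    Uses the exact permutation null when both groups have at most
    ``EXACT_MAX_N`` observations and the pooled data are tie-free;
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and no_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)


def compare_groups(results) -> MtDnaComparison:
    """Compare mtDNA ratios of euploid vs chromosomally abnormal embryos.

    *results* is an iterable of objects with ``classification`` and
    ``mito_ratio`` attributes (e.g. :class:`~embryoscreen.pipeline.EmbryoResult`).
    """
    eup = [r.mito_ratio for r in results if r.classification == CLASS_EUPLOID]
    abn = [r.mito_ratio for r in results if r.classification != CLASS_EUPLOID]
    if not eup or not abn:
        raise InsufficientDataError(
            "need at least one euploid and one abnormal embryo"
        )
    U, p = mann_whitney(eup, abn)
    med_e, med_a = float(np.median(eup)), float(np.median(abn))
    if med_a > med_e:
        direction = "abnormal greater"
    elif med_e > med_a:
        direction = "euploid greater"
    else:
        direction = "no difference"
    return MtDnaComparison(tuple(eup), tuple(abn), U, p, direction)
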