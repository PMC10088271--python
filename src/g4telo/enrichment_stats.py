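"""Inferential summaries: outlier status of telomeric element PQS counts
within a LINE clade, and strand-asymmetry of PQS counts within a family.

Telomeric retrotransposons are expected to sit in the upper tail of
quadruplex-count distributions of their clade; a Tukey fence (Q3 + k*IQR,
k = 1.5) with percentile ranks makes that claim auditable under other
conventions.  Strand asymmetry uses an exact two-sided binomial test —
per-family counts are small, so a normal approximation would be unreliable.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


class InsufficientDataError(ValueError):
    pass


@dataclass(frozen=True)
class OutlierReport:
    clade: str
    values: tuple[float, ...]
    q1: float
    q3: float
    iqr: float
    upper_fence: float
    flagged: frozenset[str]
    percentile_rank: Mapping[str, float]


def tukey_upper_outliers(
    values: Sequence[float],
    ids: Sequence[str] | None = None,
    k: float = 1.5,
    clade: str = "",
    query: Sequence[str] | None = None,
) -> OutlierReport:
    """Flag values above Q3 + k*IQR.

    Quartiles use linear interpolation on the order statistics (quantile q
    at rank (n-1)*q, the numpy default).  ``percentile_rank`` reports, for
    each queried element (default: all), the percent of values <= its value.
    """
    if len(values) < 4:
        raise InsufficientDataError("need >= 4 values for quartile-based fences")
    if ids is None:
        ids = [str(i) for i in range(len(values))]
    if len(ids) != len(values):
        raise ValueError("ids and values differ in length")
    arr = np.asarray(values, dtype=float)
    q1, q3 = np.quantile(arr, [0.25, 0.75])  # linear interpolation ("type 7")
    iqr = q3 - q1
    fence = q3 + k * iqr
    flagged = frozenset(i for i, v in zip(ids, values) if v > fence)
    ordered = sorted(values)
    n = len(values)
    which = ids if query is None else query
    value_of = dict(zip(ids, values))
    ranks = {i: 100.0 * bisect_right(ordered, value_of[i]) / n for i in which}
    return OutlierReport(
        clade=clade,
        values=tuple(values),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        upper_fence=float(fence),
        flagged=flagged,
        percentile_rank=ranks,
    )


def strand_asymmetry_test(n_sense: int, n_antisense: int) -> dict[str, float]:
    """Asymmetry index and exact two-sided binomial p under p = 0.5.

    index = |n_sense - n_antisense| / total; p sums the probabilities of all
    outcomes no more probable than the observed count.
    """
    if n_sense < 0 or n_antisense < 0:
        raise ValueError("counts must be non-negative")
    total = n_sense + n_antisense
    if total < 1:
        raise ValueError("at least one PQS required")
    index = abs(n_sense - n_antisense) / total
    p = stats.binomtest(n_sense, total, 0.5, alternative="two-sided").pvalue
    return {"asymmetry_index": index, "p_two_sided": float(p)}
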