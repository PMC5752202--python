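"""Expression change by domain class and qPCR-style summary statistics.

Expression tables are pandas DataFrames (genes x samples, raw counts).
``log2_ratio_by_class`` computes per-gene log2(strain/WT) on library-size
normalized counts, grouping genes by the differential domain class
(gained / lost) that fully contains them; genes outside any changed region
form the control class. ``qpcr_summary`` reproduces mean / SD / 95% CI
reporting for replicate measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .domain_analysis import DomainCall, DomainCallSet, GAINED, LOST

CONTROL = "control"

# z quantile used for the 95% CI. The normal approximation (not a
# t-quantile) is used deliberately: it reproduces published qPCR intervals
# computed this way at n=3. A reproduction choice, not an endorsement.
Z_95 = 1.96


@dataclass(frozen=True)
class QpcrSummary:
    mean: float
    sd: float
    n: int
    ci_lo: float
    ci_hi: float

    def __post_init__(self):
        if not (self.ci_lo <= self.mean <= self.ci_hi):
            raise ValueError("CI must bracket the mean")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


def normalize_counts(table: pd.DataFrame, total: float = 1_000_000.0) -> pd.DataFrame:
    """Scale every sample (column) to the same library total.

    Counts-per-million by default; divide by 1000 for display as
    counts/1000.
    """
    sums = table.sum(axis=0)
    if (sums <= 0).any():
        bad = sums[sums <= 0].index.tolist()
        raise ValueError(f"zero-total sample(s): {bad}")
    return table / sums * total


def five_number(values: Sequence[float]) -> Optional[Dict[str, float]]:
    """Min / Q1 / median / Q3 / max, or ``None`` for an empty class."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return None
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"min": float(v.min()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(v.max())}


def _class_of_gene(gene, changed: List[DomainCall]) -> Optional[str]:
    """gained/lost if fully inside a labeled interval; CONTROL if outside all
    changed intervals; None (excluded) on partial overlap."""
    touches = None
    for c in changed:
        if c.chrom != gene.chrom:
            continue
        if c.start <= gene.start and gene.end <= c.end:
            return c.label
        if gene.start < c.end and c.start < gene.end:
            touches = True
    return None if touches else CONTROL


def log2_ratio_by_class(table: pd.DataFrame, strain: str, wt: str,
                        class_intervals, genes: Sequence,
                        pseudocount: float = 1.0):
    """Per-class log2(strain/WT) values plus five-number summaries.

    ``class_intervals`` is a :class:`DomainCallSet` (or iterable of calls)
    whose ``gained``/``lost`` labels define the changed regions, in the same
    coordinates as ``genes``.
    """
    for s in (strain, wt):
        if s not in table.columns:
            raise KeyError(f"sample {s!r} missing from expression table")
    calls = list(class_intervals)
    changed = [c for c in calls if c.label in (GAINED, LOST)]
    norm = normalize_counts(table[[strain, wt]])
    values: Dict[str, List[float]] = {GAINED: [], LOST: [], CONTROL: []}
    for g in genes:
        klass = _class_of_gene(g, changed)
        if klass is None or g.gene_id not in norm.index:
            continue
        a = norm.at[g.gene_id, strain] + pseudocount
        b = norm.at[g.gene_id, wt] + pseudocount
        values[klass].append(math.log2(a / b))
    summaries = {k: five_number(v) for k, v in values.items()}
    return values, summaries


def qpcr_summary(values: Sequence[float]) -> QpcrSummary:
    """Mean, sample SD (n-1) and z-based 95% CI of replicate measurements."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two replicates")
    return summary_from_stats(float(v.mean()), float(v.std(ddof=1)), int(v.size))


def summary_from_stats(mean: float, sd: float, n: int) -> QpcrSummary:
    """CI from already-computed mean/SD (e.g. published values)."""
    if n < 2:
        raise ValueError("need n >= 2")
    half = Z_95 * sd / math.sqrt(n)
    return QpcrSummary(mean, sd, n, mean - half, mean + half)


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float],
                 variant: str = "pooled",
                 tail: str = "two") -> Tuple[float, float, float]:
    """t statistic, degrees of freedom and p-value.

    ``variant`` selects the pooled-variance or Welch test; ``tail`` 'one'
    reports the one-sided p for the alternative mean(a) > mean(b). Two
    zero-variance groups with equal means yield (0, df, 1).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise ValueError("variant must be 'pooled' or 'welch'")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")

    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            df = na + nb - 2
            return 0.0, float(df), 1.0
        t = math.inf if a.mean() > b.mean() else -math.inf
        p_two = 0.0
        df = float(na + nb - 2)
        return t, df, (0.0 if tail == "two" or t > 0 else 1.0)

    if variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = float(na + nb - 2)
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = float((a.mean() - b.mean()) / se)
    if tail == "two":
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:
        p = float(stats.t.sf(t, df))
    return t, float(df), p
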