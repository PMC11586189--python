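"""Nonparametric group comparisons and screening-count summaries.

Kruskal–Wallis (tie-corrected, chi-square approximation) screens for any
difference among k groups of replicate measurements; Dunn's rank-mean z
tests resolve which pairs differ, with a configurable multiplicity
adjustment (Holm by default).  ``screening_summary`` turns positive/total
isolate counts into display percentages with optional set-arithmetic
cross-checks for two-compound screens.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupedMeasurements",
    "TestResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "screening_summary",
    "adjust_pvalues",
]


@dataclass
class GroupedMeasurements:
    """Named groups of real-valued replicate measurements."""

    groups: dict[str, list[float]]

    def __post_init__(self) -> None:
        for label, vals in self.groups.items():
            if len(vals) == 0:
                raise ValueError(f"group {label!r} has no observations")
            arr = np.asarray(vals, dtype=float)
            if not np.isfinite(arr).all():
                raise ValueError(f"group {label!r} contains non-finite values")

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.groups.values())

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """All measurements and a parallel array of group labels."""
        vals = np.concatenate([np.asarray(v, float) for v in self.groups.values()])
        labels = np.concatenate(
            [np.repeat(k, len(v)) for k, v in self.groups.items()]
        )
        return vals, labels


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    pairwise: pd.DataFrame | None = None


def kruskal_wallis(g: GroupedMeasurements) -> TestResult:
    """Kruskal–Wallis H test with tie correction.

    df = k - 1; the p-value comes from the chi-square approximation
    regardless of sample size.  When every observation is identical the
    statistic is taken as its limiting value 0 with p = 1 (scipy refuses
    this degenerate case).
    """
    if len(g.groups) < 2:
        raise ValueError("need at least 2 groups")
    if g.n_total < 3:
        raise ValueError("need at least 3 observations in total")
    vals, _ = g.pooled()
    df = len(g.groups) - 1
    if np.all(vals == vals[0]):
        return TestResult(statistic=0.0, df=df, p_value=1.0, method="kruskal-wallis")
    h, p = stats.kruskal(*[np.asarray(v, float) for v in g.groups.values()])
    return TestResult(statistic=float(h), df=df, p_value=float(p),
                      method="kruskal-wallis")


def adjust_pvalues(p: np.ndarray, method: str = "holm") -> np.ndarray:
    """Multiple-testing adjustment: none, bonferroni, holm, or bh.

    All adjusted values are clipped to [raw p, 1].  Holm and BH use the
    standard step-down / step-up monotonicity enforcement.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if method == "none" or m == 0:
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    if method == "holm":
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            out[idx] = min(running, 1.0)
        return out
    if method == "bh":
        sorted_p = p[order]
        scaled = sorted_p * m / (np.arange(m) + 1)
        monotone = np.minimum.accumulate(scaled[::-1])[::-1]
        out[order] = np.minimum(monotone, 1.0)
        return out
    raise ValueError(f"unknown adjustment method {method!r}")


def dunn_posthoc(g: GroupedMeasurements, adjustment: str = "holm") -> TestResult:
    """Dunn's post-hoc pairwise rank-mean tests following Kruskal–Wallis.

    For groups i, j with mean ranks R̄_i, R̄_j over the pooled mid-ranked
    data of size N:

        z = (R̄_i - R̄_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))

    where T = Σ(t³ - t)/(12(N-1)) over tie groups of size t.  Two-sided
    p-values are adjusted by ``adjustment`` (default Holm).
    """
    omnibus = kruskal_wallis(g)
    vals, labels = g.pooled()
    n = len(vals)
    ranks = stats.rankdata(vals)  # mid-ranks for ties
    mean_rank = {lab: float(ranks[labels == lab].mean()) for lab in g.labels}
    sizes = {lab: int((labels == lab).sum()) for lab in g.labels}
    _, tie_counts = np.unique(vals, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for a, b in itertools.combinations(g.labels, 2):
        denom2 = var_base * (1.0 / sizes[a] + 1.0 / sizes[b])
        if denom2 <= 0:
            z = 0.0  # all observations tied: no rank variation at all
        else:
            z = (mean_rank[a] - mean_rank[b]) / math.sqrt(denom2)
        rows.append((a, b, z, 2.0 * stats.norm.sf(abs(z))))
    pairwise = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p_raw"])
    pairwise["p_adjusted"] = adjust_pvalues(pairwise["p_raw"].values, adjustment)
    return TestResult(
        statistic=omnibus.statistic,
        df=omnibus.df,
        p_value=omnibus.p_value,
        method=f"dunn ({adjustment})",
        pairwise=pairwise,
    )


@dataclass
class ScreeningSummary:
    """Percentages of positive isolates per label, with set cross-checks."""

    table: pd.DataFrame
    total: int
    both: int | None = None
    both_crosscheck: int | None = None
    consistent: bool | None = None


def screening_summary(
    positives: dict[str, int],
    total: int,
    exclusives: dict[str, int] | None = None,
) -> ScreeningSummary:
    """Percent of isolates positive per label, with exact set arithmetic.

    ``percentage`` is 100 * count / total, rounded to one decimal for
    display (full precision retained in ``fraction``).  When exactly two
    labels carry exclusive counts (positives able to grow on that compound
    only), the overlap is derived both ways — positives_A - exclusive_A and
    positives_B - exclusive_B — and an inconsistency is flagged in the
    result, never silently reconciled.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    for label, count in positives.items():
        if not (0 <= count <= total):
            raise ValueError(f"count for {label!r} ({count}) outside [0, {total}]")
    rows = []
    for label, count in positives.items():
        frac = count / total
        rows.append((label, count, frac, round(100.0 * frac, 1)))
    table = pd.DataFrame(rows, columns=["label", "count", "fraction", "percentage"])
    both = crosscheck = consistent = None
    if exclusives is not None:
        unknown = set(exclusives) - set(positives)
        if unknown:
            raise ValueError(f"exclusive counts for unknown labels {sorted(unknown)}")
        if len(exclusives) == 2:
            (la, ea), (lb, eb) = exclusives.items()
            both = positives[la] - ea
            crosscheck = positives[lb] - eb
            consistent = both == crosscheck
    return ScreeningSummary(
        table=table, total=total, both=both, both_crosscheck=crosscheck,
        consistent=consistent,
    )
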