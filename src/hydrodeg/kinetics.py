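"""Degradation accounting and first-order kinetics with a fixed 100% intercept.

Two bookkeeping conventions run through flask and greenhouse experiments:

* removal is always expressed against the mean of heat-killed controls, so
  that abiotic losses (volatilisation, extraction) cancel out of the
  biological signal;
* decay over time is modelled as first-order on the natural-log scale with
  the intercept pinned at 100% at the starting time, ln y(t) = ln 100 + b t,
  so the slope is minus the rate constant and t1/2 = ln 2 / (-b).

With the intercept fixed, the least-squares slope has the closed form

    b = sum_i t_i (ln y_i - ln 100) / sum_i t_i^2

which is used directly (no pseudo-observation tricks), making the estimator
exact and easy to cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import DecayExperiment, DecayRecord

__all__ = [
    "RemovalResult",
    "KineticsFit",
    "DecayComparison",
    "removal_percent",
    "fit_first_order",
    "compare_decay",
    "abiotic_loss",
]


@dataclass
class RemovalResult:
    """Per-replicate percent removal relative to heat-killed controls.

    removal = 100 * (1 - c / mean(controls)); residual = 100 - removal.
    Negative removals (sample above the control mean) are reported as-is,
    never clipped — truncation at zero would bias replicate means.
    """

    compound: str
    removal_pct: np.ndarray
    control_mean: float
    n_control: int
    n_sample: int

    @property
    def residual_pct(self) -> np.ndarray:
        return 100.0 - self.removal_pct

    @property
    def mean_removal(self) -> float:
        return float(np.mean(self.removal_pct))

    @property
    def se_removal(self) -> float:
        if self.n_sample < 2:
            return float("nan")
        return float(np.std(self.removal_pct, ddof=1) / math.sqrt(self.n_sample))


def removal_percent(
    samples, controls, compound: str = ""
) -> RemovalResult:
    """Percent removal of each sample replicate against the control mean."""
    controls = np.asarray(controls, dtype=float)
    samples = np.asarray(samples, dtype=float)
    if controls.size == 0:
        raise ValueError("no control replicates")
    cmean = float(controls.mean())
    if cmean <= 0:
        raise ValueError(f"control mean must be positive, got {cmean}")
    removal = 100.0 * (1.0 - samples / cmean)
    return RemovalResult(
        compound=compound,
        removal_pct=removal,
        control_mean=cmean,
        n_control=int(controls.size),
        n_sample=int(samples.size),
    )


@dataclass
class KineticsFit:
    """First-order fit for one condition: slope on ln-residual scale, half-life.

    The fitted curve passes exactly through ``intercept_pct`` (default 100%)
    at t = 0; ``half_life`` is ln 2 / (-slope) in the experiment's time unit,
    +inf when the slope is non-negative (no decay).
    """

    condition: str
    slope_b: float
    window: tuple[float, float]
    n_points: int
    rss: float
    intercept_pct: float = 100.0
    time_unit: str = "days"

    @property
    def half_life(self) -> float:
        if self.slope_b >= 0:
            return float("inf")
        return math.log(2.0) / (-self.slope_b)

    def residual_at(self, t) -> np.ndarray:
        """Model-predicted residual percent at times ``t``."""
        return self.intercept_pct * np.exp(self.slope_b * np.asarray(t, dtype=float))


def _residual_percent(
    e: DecayExperiment, records: list[DecayRecord]
) -> np.ndarray:
    """Concentrations as percent of the starting level.

    A ``percent`` concentration unit is taken at face value; any other unit
    is normalised to the condition's mean concentration at the experiment's
    earliest time (the 100% anchor the fixed intercept refers to).
    """
    conc = np.array([r.concentration for r in records], dtype=float)
    if e.concentration_unit in ("percent", "%"):
        return conc
    t0 = e.t0
    ref = [r.concentration for r in records if r.time == t0]
    if not ref:
        raise ValueError(
            f"condition {records[0].condition!r} has no record at t={t0} "
            "to anchor the 100% reference"
        )
    ref_mean = float(np.mean(ref))
    if ref_mean <= 0:
        raise ValueError("starting-time mean concentration must be positive")
    return 100.0 * conc / ref_mean


def _window_records(records, window):
    lo, hi = window
    if hi < lo:
        raise ValueError(f"empty window {window}")
    return [r for r in records if lo <= r.time <= hi]


def fit_first_order(
    e: DecayExperiment,
    condition: str,
    window: tuple[float, float] | None = None,
    intercept_pct: float = 100.0,
) -> KineticsFit:
    """Fixed-intercept log-linear fit of residual percent over time.

    ``window`` restricts the fit to ``t_start <= t <= t_end`` (default: full
    series); both the early-window and full-series fits are explicit choices,
    never inferred from the data.
    """
    records = e.subset(condition)
    if window is None:
        window = (min(r.time for r in records), max(r.time for r in records))
    used = _window_records(records, window)
    times = np.array([r.time for r in used], dtype=float)
    if len(np.unique(times)) < 2:
        raise ValueError(
            f"condition {condition!r}: fewer than 2 distinct time points in "
            f"window {window}"
        )
    resid = _residual_percent(e, used)
    for r, y in zip(used, resid):
        if y <= 0:
            raise ValueError(
                f"non-positive residual {y}% at t={r.time} "
                f"({r.condition}, rep {r.replicate}): cannot log-transform"
            )
    dev = np.log(resid) - math.log(intercept_pct)
    denom = float(np.sum(times**2))
    if denom == 0:
        raise ValueError("all records at t=0; no slope information")
    b = float(np.sum(times * dev) / denom)
    rss = float(np.sum((dev - b * times) ** 2))
    return KineticsFit(
        condition=condition,
        slope_b=b,
        window=window,
        n_points=len(used),
        rss=rss,
        intercept_pct=intercept_pct,
        time_unit=e.time_unit,
    )


@dataclass
class DecayComparison:
    """Per-condition slopes plus pairwise slope-difference t tests."""

    fits: dict[str, KineticsFit]
    contrasts: pd.DataFrame
    variance: str
    df_pooled: int

    def fit(self, condition: str) -> KineticsFit:
        return self.fits[condition]


def compare_decay(
    e: DecayExperiment,
    conditions: list[str],
    window: tuple[float, float] | None = None,
    intercept_pct: float = 100.0,
    variance: str = "pooled",
) -> DecayComparison:
    """Compare decay slopes across conditions under a common 100% intercept.

    Equivalent to one regression of ln-residual deviations on per-condition
    time dummies with no intercept: the design is block-orthogonal, so each
    condition's slope equals its separate fixed-intercept fit.  Pairwise
    contrasts use a pooled residual variance with df = n_total - k by
    default; ``variance="per_condition"`` switches to a Welch-type contrast
    with Satterthwaite degrees of freedom.
    """
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions to compare")
    if variance not in ("pooled", "per_condition"):
        raise ValueError(f"unknown variance mode {variance!r}")
    fits = {
        c: fit_first_order(e, c, window=window, intercept_pct=intercept_pct)
        for c in conditions
    }
    # Sum over each condition's in-window t_i^2: the slope's design leverage.
    st2: dict[str, float] = {}
    for c in conditions:
        records = _window_records(e.subset(c), fits[c].window)
        times = np.array([r.time for r in records], dtype=float)
        st2[c] = float(np.sum(times**2))
    n_total = sum(fits[c].n_points for c in conditions)
    k = len(conditions)
    df_pooled = n_total - k
    rss_total = sum(fits[c].rss for c in conditions)
    rows = []
    for i, ci in enumerate(conditions):
        for cj in conditions[i + 1:]:
            diff = fits[ci].slope_b - fits[cj].slope_b
            if variance == "pooled":
                if df_pooled <= 0:
                    raise ValueError("no residual degrees of freedom for pooled test")
                s2 = rss_total / df_pooled
                var = s2 * (1.0 / st2[ci] + 1.0 / st2[cj])
                df = float(df_pooled)
            else:
                dfi = fits[ci].n_points - 1
                dfj = fits[cj].n_points - 1
                if dfi <= 0 or dfj <= 0:
                    raise ValueError("per-condition variance needs >=2 points per condition")
                vi = (fits[ci].rss / dfi) / st2[ci]
                vj = (fits[cj].rss / dfj) / st2[cj]
                var = vi + vj
                df = (vi + vj) ** 2 / (vi**2 / dfi + vj**2 / dfj) if var > 0 else 1.0
            if var == 0:
                tstat = 0.0 if diff == 0 else math.copysign(math.inf, diff)
                p = 1.0 if diff == 0 else 0.0
            else:
                tstat = diff / math.sqrt(var)
                p = float(2.0 * stats.t.sf(abs(tstat), df))
            rows.append((ci, cj, diff, tstat, df, p))
    contrasts = pd.DataFrame(
        rows, columns=["condition_i", "condition_j", "slope_diff", "t", "df", "p_value"]
    )
    return DecayComparison(fits=fits, contrasts=contrasts, variance=variance,
                           df_pooled=df_pooled)


def abiotic_loss(e: DecayExperiment, control_condition: str) -> pd.DataFrame:
    """Percent loss over time in an abiotic (sterilised / heat-killed) control.

    loss(t) = 100 * (1 - mean_c(t) / mean_c(t0)), with t0 the earliest time
    of the control series.  Negative losses (apparent gains, within
    measurement noise) are reported as-is.
    """
    records = e.subset(control_condition)
    t0 = min(r.time for r in records)
    ref = [r.concentration for r in records if r.time == t0]
    if not ref:
        raise ValueError(
            f"control condition {control_condition!r} lacks an earliest-time reference"
        )
    ref_mean = float(np.mean(ref))
    if ref_mean <= 0:
        raise ValueError("reference mean concentration must be positive")
    times = sorted({r.time for r in records})
    rows = []
    for t in times:
        vals = [r.concentration for r in records if r.time == t]
        mean_t = float(np.mean(vals))
        rows.append((t, mean_t, 100.0 * (1.0 - mean_t / ref_mean), len(vals)))
    return pd.DataFrame(rows, columns=["time", "mean_concentration", "loss_pct", "n"])
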