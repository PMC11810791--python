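"""Kaplan-Meier estimation and the two-group log-rank test.

Used to associate CTC-IGC positivity (or a binary expression split) with
progression-free survival.  The product-limit estimator uses the standard
simultaneous-death tie convention, with censoring at an event time placed
after the event (censored subjects count as at risk at that time).
Greenwood's formula provides pointwise variances.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["KMCurve", "km_estimate", "km_by_group", "logrank_test", "median_split"]


@dataclasses.dataclass
class KMCurve:
    """A Kaplan-Meier step function with Greenwood variances.

    ``times`` are the distinct event times; ``survival[i]`` is S(t) just
    after ``times[i]``.  S(0) = 1 is implicit.
    """

    times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        s = np.asarray(self.survival)
        if len(s) and (np.any(np.diff(s) > 1e-12) or np.any(s < -1e-12) or np.any(s > 1 + 1e-12)):
            raise ValueError("survival must be non-increasing within [0, 1]")

    @property
    def std_err(self) -> np.ndarray:
        return np.sqrt(self.greenwood_var)

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
                "std_err": self.std_err,
            }
        )


def km_estimate(time, event) -> KMCurve:
    """Product-limit estimate of the survival function.

    ``event`` is True/1 for an observed event (progression), False/0 for
    right censoring.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("need at least one subject")
    if np.any(time < 0):
        raise ValueError("times must be >= 0")
    ev_times = np.unique(time[event])
    n = time.size
    at_risk = np.array([(time >= t).sum() for t in ev_times], dtype=int)
    d = np.array([((time == t) & event).sum() for t in ev_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    green = surv**2 * np.cumsum(d / (at_risk * (at_risk - d).clip(min=1)).astype(float))
    # when d == n_at_risk the survival hits 0 and Greenwood is conventionally 0
    green[surv == 0] = 0.0
    return KMCurve(
        times=ev_times,
        at_risk=at_risk,
        n_events=d,
        survival=surv,
        greenwood_var=green,
        n_subjects=n,
    )


def km_by_group(table: pd.DataFrame, group_col: str = "group",
                time_col: str = "time", event_col: str = "event") -> dict:
    """KM curve per level of ``group_col``; errors on an empty group."""
    out = {}
    for g, sub in table.groupby(group_col):
        if len(sub) == 0:
            raise ValueError(f"group {g!r} is empty")
        out[g] = km_estimate(sub[time_col], sub[event_col])
    if not out:
        raise ValueError("no groups in table")
    return out


def logrank_test(time, event, group) -> tuple[float, float]:
    """Standard two-group log-rank test; returns (chi2 statistic, p).

    The statistic is (sum(O1 - E1))^2 / sum(V) over distinct event times,
    with hypergeometric variance V at each time; p is from chi-square with
    1 degree of freedom.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    g1 = group == levels[0]
    if g1.all() or (~g1).all():
        raise ValueError("one group is empty")
    if not event.any():
        raise ValueError("need at least one event")
    ev_times = np.unique(time[event])
    o_minus_e = 0.0
    var = 0.0
    for t in ev_times:
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & event).sum()
        d1 = ((time == t) & event & g1).sum()
        if n <= 1:
            continue
        e1 = d * n1 / n
        v = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        o_minus_e += d1 - e1
        var += v
    if var <= 0:
        return 0.0, 1.0  # no between-group information (e.g. identical groups)
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def median_split(values) -> np.ndarray:
    """Boolean high-expression grouping at the median (>= median is high)."""
    values = np.asarray(values, dtype=float)
    return values >= np.median(values)
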