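"""Kaplan-Meier estimation, log-rank comparisons, O/E hazard ratios.

Survival input is a clinical table with one row per patient per endpoint
(disease-free or overall survival), a nonnegative follow-up time, an event
indicator (1 = event observed, 0 = right-censored) and a subtype label.
Pairwise group comparisons use the standard two-group log-rank statistic;
hazard ratios come from the observed/expected (Pike) estimator of the same
log-rank table, HR = (O_A/E_A)/(O_B/E_B) with log-HR standard error
sqrt(1/E_A + 1/E_B).  The k-group log-rank test is delegated to lifelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import chi2

from .containers import validate_survival_table

__all__ = ["KMCurve", "LogrankResult", "km_estimate", "survival_at",
           "logrank_pair", "multigroup_logrank", "bonferroni",
           "event_redistribution"]

log = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit estimate: survival drops at each distinct event time."""

    event_times: np.ndarray  # distinct times with >= 1 event, ascending
    survival: np.ndarray     # S(t) just after each event time, non-increasing
    at_risk: np.ndarray      # n at risk at each event time
    n_events: np.ndarray     # events at each event time
    max_followup: float      # last observed time (event or censoring)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.survival) > 1e-12):
            raise ValueError("survival curve must be non-increasing")


def _endpoint_slice(table: pd.DataFrame, endpoint: str | None) -> pd.DataFrame:
    table = validate_survival_table(table)
    if endpoint is not None:
        table = table[table["endpoint"] == endpoint]
    elif table["endpoint"].nunique() > 1:
        raise ValueError("table mixes endpoints; pass endpoint= to select one")
    return table


def km_estimate(table: pd.DataFrame, group: str,
                endpoint: str | None = None) -> KMCurve:
    """Kaplan-Meier product-limit estimator for one subtype group.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i); patients censored exactly at an
    event time are counted at risk at that time.
    """
    t = _endpoint_slice(table, endpoint)
    t = t[t["subtype"] == group]
    if len(t) == 0:
        raise ValueError(f"empty group {group!r}")
    times = t["time"].to_numpy()
    events = t["event"].to_numpy()
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv, at_risk, d_counts = [], [], []
    s = 1.0
    for et in event_times:
        n_i = int((times >= et).sum())  # censored-at-event-time still at risk
        d_i = int(((times == et) & (events == 1)).sum())
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        d_counts.append(d_i)
    return KMCurve(event_times=event_times, survival=np.asarray(surv),
                   at_risk=np.asarray(at_risk), n_events=np.asarray(d_counts),
                   max_followup=float(times.max()))


def survival_at(curve: KMCurve, t: float) -> float:
    """Evaluate the KM curve as a right-continuous step function at time t."""
    if t < 0:
        raise ValueError("time must be >= 0")
    if t > curve.max_followup:
        warnings.warn(f"t={t} beyond last follow-up {curve.max_followup}; "
                      "returning last estimate")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    return 1.0 if idx < 0 else float(curve.survival[idx])


@dataclass
class LogrankResult:
    chi2: float
    p_value: float
    hr: float | None          # O/E hazard ratio of group A vs group B
    ci_low: float | None
    ci_high: float | None
    observed: dict[str, float]
    expected: dict[str, float]


def _oe_table(times: np.ndarray, events: np.ndarray,
              in_a: np.ndarray) -> tuple[float, float, float, float, float]:
    """Observed/expected events for group A and hypergeometric variance."""
    o_a = e_a = v = 0.0
    o_b = e_b = 0.0
    for et in np.unique(times[events == 1]):
        at_risk = times >= et
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((times == et) & (events == 1)).sum())
        d_a = int(((times == et) & (events == 1) & in_a).sum())
        o_a += d_a
        o_b += d - d_a
        e = d * n_a / n
        e_a += e
        e_b += d - e
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_a, e_a, o_b, e_b, v


def logrank_pair(table: pd.DataFrame, group_a: str, group_b: str,
                 endpoint: str | None = None) -> LogrankResult:
    """Two-group log-rank test with an O/E hazard ratio and 95% CI.

    The chi-square statistic is (O_A - E_A)^2 / V with the hypergeometric
    variance V summed over event times (1 df).  When a group has zero
    expected events the HR is undefined and reported as None.
    """
    t = _endpoint_slice(table, endpoint)
    t = t[t["subtype"].isin([group_a, group_b])]
    for g in (group_a, group_b):
        if (t["subtype"] == g).sum() == 0:
            raise ValueError(f"empty group {g!r}")
    if t["event"].sum() == 0:
        raise ValueError("no events in either group")
    times = t["time"].to_numpy()
    events = t["event"].to_numpy()
    in_a = (t["subtype"] == group_a).to_numpy()
    o_a, e_a, o_b, e_b, v = _oe_table(times, events, in_a)
    stat = (o_a - e_a) ** 2 / v if v > 0 else 0.0
    p = float(chi2.sf(stat, df=1)) if v > 0 else 1.0
    hr = ci_lo = ci_hi = None
    if e_a > 0 and e_b > 0 and o_a > 0 and o_b > 0:
        hr = (o_a / e_a) / (o_b / e_b)
        se = np.sqrt(1.0 / e_a + 1.0 / e_b)
        ci_lo = float(hr * np.exp(-1.96 * se))
        ci_hi = float(hr * np.exp(1.96 * se))
        hr = float(hr)
    else:
        log.warning("zero observed/expected events in a group; HR undefined for %s vs %s",
                    group_a, group_b)
    return LogrankResult(chi2=float(stat), p_value=p, hr=hr, ci_low=ci_lo,
                         ci_high=ci_hi,
                         observed={group_a: o_a, group_b: o_b},
                         expected={group_a: e_a, group_b: e_b})


def multigroup_logrank(table: pd.DataFrame,
                       endpoint: str | None = None) -> tuple[float, int, float]:
    """k-group log-rank test; returns (chi-square, df = k-1, p-value)."""
    t = _endpoint_slice(table, endpoint)
    groups = t["subtype"].unique()
    if len(groups) < 2:
        raise ValueError("need >= 2 nonempty groups")
    res = multivariate_logrank_test(t["time"], t["subtype"], t["event"])
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def bonferroni(p_values: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni adjustment: min(1, m * p) with m >= number of tests."""
    ps = list(p_values)
    if any(p < 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(ps) if m is None else m
    if m < len(ps):
        raise ValueError("m must be >= number of p-values")
    return [min(1.0, m * p) for p in ps]


def event_redistribution(table: pd.DataFrame,
                         forced: Mapping[str, str] | pd.Series,
                         endpoint: str | None = None) -> pd.DataFrame:
    """Contingency counts of good/poor outcome per forced subtype.

    For each subtype in the forced assignment, counts patients with
    event = 0 and event = 1.  Totals are conserved.
    """
    t = _endpoint_slice(table, endpoint)
    forced = pd.Series(dict(forced)) if not isinstance(forced, pd.Series) else forced
    unknown = set(forced.index) - set(t["sample_id"])
    if unknown:
        raise ValueError(f"forced map contains unknown samples: {sorted(unknown)[:5]}")
    t = t[t["sample_id"].isin(forced.index)]
    lab = t["sample_id"].map(forced)
    out = pd.crosstab(lab, t["event"]).reindex(columns=[0, 1], fill_value=0)
    out.index.name = "subtype"
    out.columns = ["event_0", "event_1"]
    return out
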