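"""Survival stratification by infiltration score.

Patients are binned by Tav (mean log2 signature expression of their tumor)
and the bins are compared with the Kaplan-Meier product-limit estimator, the
Mantel-Cox log-rank test, and a hazard ratio derived from the log-rank
observed/expected event counts:

    HR = (O_A / E_A) / (O_B / E_B),
    95% CI = exp(log HR +/- 1.96 * sqrt(1/E_A + 1/E_B)).

The product-limit and log-rank computations are implemented here directly —
the hazard ratio needs the per-group O/E that the test produces — and are
checked against lifelines in the test suite.

Default Tav bin edges are [0.125, 0.5, 2]: the outermost cuts (<0.125 and
>2) are the published ones; the intermediate 0.5 edge is a package default
(the published figure does not print it) and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TavBinning",
    "bin_by_tav",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
    "hazard_ratio_logrank",
    "welch_ttest",
    "oneway_anova",
    "stratified_km",
]

DEFAULT_EDGES = (0.125, 0.5, 2.0)


@dataclass
class TavBinning:
    """Ascending Tav bin edges; k edges define k+1 bins.

    Bin intervals are (-inf, e1), [e1, e2), ..., [e_{k-1}, e_k], (e_k, inf):
    the lowest bin is strictly below the first edge and the highest strictly
    above the last (a value exactly at the last edge falls in the bin below),
    matching the strict "<first" / ">last" convention.
    """

    edges: tuple[float, ...] = DEFAULT_EDGES
    labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("edges must be strictly increasing and non-empty")
        object.__setattr__(self, "edges", edges)
        labels = [f"<{edges[0]:g}"]
        for a, b in zip(edges, edges[1:]):
            labels.append(f"{a:g}–{b:g}")
        labels.append(f">{edges[-1]:g}")
        object.__setattr__(self, "labels", tuple(labels))

    def assign(self, value: float) -> str:
        edges = np.asarray(self.edges)
        idx = int(np.searchsorted(edges, value, side="right"))
        if value == edges[-1]:
            idx = len(edges) - 1  # exactly at the top edge -> bin below the top
        return self.labels[idx]


def bin_by_tav(
    tavs: Sequence[float] | pd.Series, binning: TavBinning | None = None
) -> pd.Series:
    """Assign each Tav value to its bin label (see :class:`TavBinning`)."""
    binning = binning or TavBinning()
    s = pd.Series(tavs, dtype=float)
    return s.map(binning.assign)


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size != e.size:
        raise ValueError("times and events differ in length")
    if t.size == 0:
        raise ValueError("no records")
    if (t <= 0).any():
        raise ValueError("all times must be > 0")
    return t, e


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate of the survival function.

    Returns a DataFrame with one row per distinct event time: columns
    ``time``, ``at_risk``, ``events`` and ``survival`` (the step value just
    after that time). Censored-only times do not create steps.
    """
    t, e = _as_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = t.size
    rows = []
    surv = 1.0
    for et in event_times:
        at_risk = int((t >= et).sum())
        d = int(((t == et) & e).sum())
        surv *= 1.0 - d / at_risk
        rows.append({"time": et, "at_risk": at_risk, "events": d, "survival": surv})
    return pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])


def km_survival_at(km: pd.DataFrame, time: float) -> float:
    """Survival probability of a :func:`km_estimate` table at a given time."""
    prior = km[km["time"] <= time]
    return 1.0 if prior.empty else float(prior["survival"].iloc[-1])


@dataclass
class LogrankResult:
    chi2: float
    p_value: float
    df: int
    observed: pd.Series  # per-group observed events O_g
    expected: pd.Series  # per-group expected events E_g


def logrank_test(groups: Mapping[str, tuple[Sequence, Sequence]]) -> LogrankResult:
    """Mantel-Cox log-rank test across two or more groups.

    ``groups`` maps a label to ``(times, events)``. At each distinct event
    time, expected events per group are allocated in proportion to the
    numbers at risk; the chi-square statistic uses the full hypergeometric
    covariance of the observed-minus-expected vector (df = k-1).
    """
    if len(groups) < 2:
        raise ValueError("log-rank test requires at least two groups")
    labels = list(groups)
    arrays = {g: _as_arrays(*groups[g]) for g in labels}
    all_t = np.concatenate([arrays[g][0] for g in labels])
    all_e = np.concatenate([arrays[g][1] for g in labels])
    if not all_e.any():
        raise ValueError("log-rank test requires at least one observed event")
    event_times = np.unique(all_t[all_e])

    k = len(labels)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for et in event_times:
        n_g = np.array([(arrays[g][0] >= et).sum() for g in labels], dtype=float)
        d_g = np.array(
            [((arrays[g][0] == et) & arrays[g][1]).sum() for g in labels],
            dtype=float,
        )
        n = n_g.sum()
        d = d_g.sum()
        O += d_g
        E += d * n_g / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            p = n_g / n
            V += factor * (np.diag(p) - np.outer(p, p))

    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    chi2 = float(z @ np.linalg.solve(Vsub, z)) if z.size else 0.0
    df = k - 1
    p_value = float(sps.chi2.sf(chi2, df))
    return LogrankResult(
        chi2=chi2,
        p_value=p_value,
        df=df,
        observed=pd.Series(O, index=labels, name="observed"),
        expected=pd.Series(E, index=labels, name="expected"),
    )


def hazard_ratio_logrank(
    times_a, events_a, times_b, events_b
) -> dict[str, float | tuple[float, float]]:
    """Hazard ratio of group A vs B by the log-rank (O/E) method, with 95% CI.

    HR = (O_A/E_A)/(O_B/E_B); CI95 = exp(log HR +/- 1.96*sqrt(1/E_A + 1/E_B)).
    """
    res = logrank_test({"A": (times_a, events_a), "B": (times_b, events_b)})
    o_a, o_b = res.observed["A"], res.observed["B"]
    e_a, e_b = res.expected["A"], res.expected["B"]
    if e_a == 0 or e_b == 0:
        raise ValueError("expected event count is zero in one group")
    if o_a == 0 or o_b == 0:
        raise ValueError("observed event count is zero in one group; HR undefined on the log scale")
    hr = (o_a / e_a) / (o_b / e_b)
    half_width = 1.96 * np.sqrt(1.0 / e_a + 1.0 / e_b)
    ci = (float(hr * np.exp(-half_width)), float(hr * np.exp(half_width)))
    return {"hr": float(hr), "ci95": ci, "chi2": res.chi2, "p_value": res.p_value}


def stratified_km(
    records: pd.DataFrame,
    binning: TavBinning | None = None,
    tav_col: str = "tav",
    time_col: str = "time_days",
    event_col: str = "event",
) -> dict:
    """Bin a survival table by Tav and compare bins.

    Returns per-bin KM tables, the overall log-rank test, and the hazard
    ratio of the lowest vs the highest bin (the published contrast).
    """
    binning = binning or TavBinning()
    bins = bin_by_tav(records[tav_col].to_numpy(), binning)
    bins.index = records.index
    groups = {}
    for label in binning.labels:
        sub = records[bins == label]
        if len(sub):
            groups[label] = (
                sub[time_col].to_numpy(),
                sub[event_col].to_numpy(dtype=bool),
            )
    if len(groups) < 2:
        raise ValueError("fewer than two non-empty Tav bins")
    km = {label: km_estimate(*groups[label]) for label in groups}
    logrank = logrank_test(groups)
    result = {"bins": bins, "km": km, "logrank": logrank}
    lo, hi = binning.labels[0], binning.labels[-1]
    if lo in groups and hi in groups:
        result["hr_lowest_vs_highest"] = hazard_ratio_logrank(*groups[lo], *groups[hi])
    return result


# Thin wrappers over routine statistics -------------------------------------

def welch_ttest(a, b) -> tuple[float, float]:
    """Unpaired t-test with Welch's correction; returns (t, p)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def oneway_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA across groups; returns (F, p)."""
    res = sps.f_oneway(*[np.asarray(g, float) for g in groups])
    return float(res.statistic), float(res.pvalue)
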