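"""Kaplan-Meier estimation and log-rank comparison of two groups.

Thin wrapper over lifelines: the product-limit estimator per group and the
standard one-degree-of-freedom log-rank chi-square.  A group with no
observed events makes the comparison non-estimable and is flagged rather
than silently producing p = NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = ["km_logrank", "KMResult"]


@dataclass
class KMResult:
    chi2: float
    p: float
    estimable: bool
    curves: dict[str, pd.DataFrame]
    n_events: dict[str, int]


def km_logrank(groups: pd.Series, time: pd.Series, event: pd.Series) -> KMResult:
    """Compare survival between the two levels of ``groups``.

    All three series are aligned on their index; rows missing any value are
    dropped.  Returns KM curves per group, the log-rank chi-square (1 df)
    and its p value.
    """
    df = pd.DataFrame({"g": groups, "t": time, "e": event}).dropna()
    levels = sorted(df["g"].unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels}")
    curves: dict[str, pd.DataFrame] = {}
    n_events: dict[str, int] = {}
    for lev in levels:
        sub = df[df["g"] == lev]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["t"], event_observed=sub["e"], label=str(lev))
        curves[str(lev)] = kmf.survival_function_
        n_events[str(lev)] = int(sub["e"].sum())
    if min(n_events.values()) == 0:
        return KMResult(float("nan"), float("nan"), False, curves, n_events)
    a, b = (df[df["g"] == lev] for lev in levels)
    res = logrank_test(a["t"], b["t"], event_observed_A=a["e"], event_observed_B=b["e"])
    return KMResult(float(res.test_statistic), float(res.p_value), True, curves, n_events)
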