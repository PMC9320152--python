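"""Kaplan-Meier estimation, log-rank testing and prognostic direction.

Samples are split at the median of a per-sample score (a gene's
expression or its network degree), the High and Low groups are compared
by the two-group log-rank test, and a significant split is labelled
"positive" when the High group survives longer (higher restricted mean
survival) or "negative" when it survives shorter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import restricted_mean_survival_time

from .containers import ValidationError

__all__ = [
    "KMEstimate",
    "PrognosticCall",
    "median_split",
    "km_estimate",
    "logrank_test",
    "classify_direction",
]


@dataclass
class KMEstimate:
    """Product-limit survival estimate as a step function."""

    times: np.ndarray          # event-time grid (unique observed times)
    survival: np.ndarray       # S(t) just after each grid time
    at_risk: np.ndarray        # number at risk entering each time
    events: np.ndarray         # events at each time

    def at(self, t: float) -> float:
        """S(t); 1 before the first grid time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class PrognosticCall:
    gene: str
    layer: str                 # "expression" or "degree"
    logrank_p: float
    direction: str             # "positive", "negative" or "none"


def median_split(scores) -> np.ndarray:
    """Label samples 'High' (> median) or 'Low' (<= median).

    Ties at the median go to Low, which keeps the split deterministic.
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 4:
        raise ValidationError("median split needs at least 4 samples")
    med = float(np.median(s))
    labels = np.where(s > med, "High", "Low")
    if len(np.unique(labels)) < 2:
        raise ValidationError("all scores at or below the median; no split possible")
    return labels


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimate.

    Censored observations keep contributing to the risk set but never
    drop the curve; with no censoring the estimate equals the empirical
    survival function.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t <= 0):
        raise ValidationError("survival times must be strictly positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValidationError("event flags must be 0 or 1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tab = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index and t.min() > 0 else kmf.event_table
    grid = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(grid).to_numpy()
    return KMEstimate(
        times=grid,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        events=tab["observed"].to_numpy(dtype=int),
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p value).

    Each group is a table with 'time' and 'event' columns.  The
    statistic compares observed and expected events over the pooled
    event-time grid with the hypergeometric variance, and is referred to
    a chi-square distribution with 1 degree of freedom.
    """
    for name, g in (("A", group_a), ("B", group_b)):
        if len(g) == 0:
            raise ValidationError(f"group {name} is empty")
    total_events = int(group_a["event"].sum() + group_b["event"].sum())
    if total_events == 0:
        raise ValidationError("log-rank test needs at least one event")
    res = _ll_logrank(
        group_a["time"], group_b["time"],
        event_observed_A=group_a["event"], event_observed_B=group_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def classify_direction(table: pd.DataFrame, gene: str = "", layer: str = "",
                       alpha: float = 0.05) -> PrognosticCall:
    """Median-split prognosis of one per-sample score.

    The table needs columns (time, event, score).  Direction is
    'positive' when the split is significant and the High group has the
    larger restricted mean survival over the observed time range,
    'negative' when the Low group does, 'none' otherwise.
    """
    for col in ("time", "event", "score"):
        if col not in table.columns:
            raise ValidationError(f"survival table missing column {col!r}")
    labels = median_split(table["score"].to_numpy())
    high = table.loc[labels == "High"]
    low = table.loc[labels == "Low"]
    chi2, p = logrank_test(high, low)
    direction = "none"
    if p < alpha:
        horizon = float(table["time"].max())
        rms = {}
        for name, g in (("High", high), ("Low", low)):
            kmf = KaplanMeierFitter().fit(g["time"], event_observed=g["event"])
            rms[name] = restricted_mean_survival_time(kmf, t=horizon)
        direction = "positive" if rms["High"] > rms["Low"] else "negative"
    return PrognosticCall(gene=gene, layer=layer, logrank_p=p, direction=direction)
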