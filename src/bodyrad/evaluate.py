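"""Discrimination and risk stratification for survival scores.

Harrell's concordance index is computed by explicit pair counting: a pair is
comparable when the earlier observed time carries an event; it is concordant
when the patient with the higher (hazard-direction) score fails first, and
score ties count one half.  Confidence intervals come from a patient-level
bootstrap; the p-value tests C = 0.5 by a normal approximation over the
bootstrap spread.  Patients are stratified into low/middle/high risk at the
training score's 25th/75th percentiles; Kaplan-Meier estimation and the
k-group log-rank test compare the strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "harrell_c",
    "concordance",
    "train_cutpoints",
    "stratify_risk",
    "km_estimate",
    "logrank",
]


@dataclass
class ConcordanceResult:
    c: float
    ci_low: float
    ci_high: float
    p: float
    n_comparable_pairs: int
    n_bootstrap: int

    def __post_init__(self):
        if not (self.ci_low <= self.c <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def concordance(scores, time, event):
    """(c, n_comparable_pairs) by vectorized pair counting."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    # pair (i, j) comparable iff t_i < t_j and patient i had the event
    earlier = (t[:, None] < t[None, :]) & e[:, None]
    if not earlier.any():
        raise ValueError("no comparable pairs")
    ds = s[:, None] - s[None, :]
    conc = (earlier & (ds > 0)).sum() + 0.5 * (earlier & (ds == 0)).sum()
    n_pairs = int(earlier.sum())
    return float(conc / n_pairs), n_pairs


def harrell_c(scores, time, event, n_bootstrap=1000, seed=0,
              alpha=0.05) -> ConcordanceResult:
    """Harrell's C with percentile-bootstrap CI and a test of C = 0.5."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event).astype(bool)
    c, n_pairs = concordance(s, t, e)
    rng = np.random.default_rng(seed)
    n = len(s)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        try:
            cb, _ = concordance(s[idx], t[idx], e[idx])
        except ValueError:
            continue
        boots.append(cb)
    boots = np.asarray(boots)
    if boots.size < 2:
        raise ValueError("bootstrap failed: too few comparable resamples")
    lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
    lo, hi = min(lo, c), max(hi, c)
    sd = boots.std(ddof=1)
    if sd > 0:
        z = (c - 0.5) / sd
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        p = 1.0 if c == 0.5 else 0.0
    return ConcordanceResult(c=c, ci_low=float(lo), ci_high=float(hi), p=p,
                             n_comparable_pairs=n_pairs,
                             n_bootstrap=int(boots.size))


def train_cutpoints(train_scores):
    """(25th, 75th) percentiles of the training scores."""
    s = np.asarray(train_scores, dtype=float)
    return float(np.quantile(s, 0.25)), float(np.quantile(s, 0.75))


def stratify_risk(scores, cutpoints):
    """Assign low/middle/high risk strata from frozen training cut points.

    high: score > 75th training percentile, low: score < 25th; boundary ties
    go to the middle stratum so the extreme groups stay ≤ 25% each.
    """
    q25, q75 = cutpoints
    s = np.asarray(scores, dtype=float)
    if q25 == q75:
        warnings.warn("degenerate scores: all patients in middle stratum",
                      stacklevel=2)
        return np.full(len(s), "middle", dtype=object)
    out = np.full(len(s), "middle", dtype=object)
    out[s < q25] = "low"
    out[s > q75] = "high"
    return out


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve as a (time, survival) step table."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events).astype(int))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(),
                         "survival": sf.iloc[:, 0].to_numpy()})


def logrank(times, events, groups):
    """k-group log-rank test → (chi2, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 nonempty groups")
    if (counts == 0).any():
        raise ValueError("empty group")
    res = multivariate_logrank_test(times, groups, events)
    df = len(labels) - 1
    return float(res.test_statistic), int(df), float(res.p_value)
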