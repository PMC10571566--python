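"""Signature scoring, quartile risk groups, Kaplan-Meier and log-rank.

The fitted model's predicted event probability serves as a continuous
per-sample risk score.  Scores are discretized into risk groups using
the linear-interpolation sample quartiles (the convention where the q-th
quantile of sorted data interpolates at index 1 + (n-1)q): the 2-group
mode splits at the median, the 4-group mode at Q1/Q2/Q3.  Group survival
is summarized with the Kaplan-Meier product-limit estimator (deaths
processed before censorings at tied times) and compared with the
log-rank chi-square test; both are computed through lifelines behind
this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .enet import ElasticNetLogistic
from .exceptions import DomainError


@dataclass
class RiskGroups:
    """Quartile thresholds and the per-sample risk-group label."""

    q1: float
    q2: float
    q3: float
    labels: pd.Series
    n_groups: int


@dataclass
class SurvivalCurve:
    """Product-limit step function with its event table."""

    times: np.ndarray        # distinct observed times (events or censorings)
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray
    survival: np.ndarray     # P-hat just after each time

    def survival_at(self, t: float) -> float:
        """Step-function value of the estimator at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median_time(self) -> float:
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[below[0]]) if below.size else float("inf")


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def signature_score(fit: ElasticNetLogistic, expression: pd.DataFrame) -> pd.Series:
    """Per-sample event probability from a fitted model.

    ``expression`` is genes x samples and must cover every predictor gene
    of the fit; scores are computed for all samples passed (train and
    test alike).
    """
    missing = [g for g in fit.feature_names_in_ if g not in expression.index]
    if missing:
        raise DomainError(f"expression matrix missing predictor genes: {missing[:5]}")
    X = expression.loc[list(fit.feature_names_in_)].T
    scores = fit.predict_proba(X)[:, 1]
    return pd.Series(scores, index=expression.columns, name="signature_score")


def quartile_groups(scores, n_groups: int = 2) -> RiskGroups:
    """Split samples into risk groups at the sample quartiles.

    2-group mode: score <= Q2 (median) -> ``low``, else ``high``.
    4-group mode: lower-inclusive bins [min, Q1), [Q1, Q2), [Q2, Q3),
    [Q3, max], labelled ``Q1``..``Q4``.
    """
    scores = pd.Series(scores, dtype=float)
    if n_groups not in (2, 4):
        raise DomainError("n_groups must be 2 or 4")
    if len(scores) < n_groups:
        raise DomainError(f"need at least {n_groups} samples for {n_groups} groups")
    q1, q2, q3 = np.quantile(scores.to_numpy(), [0.25, 0.5, 0.75])  # linear interp
    if scores.nunique() == 1:
        warnings.warn("all scores identical: a single risk group results",
                      stacklevel=2)
    if n_groups == 2:
        labels = pd.Series(np.where(scores <= q2, "low", "high"),
                           index=scores.index, name="risk_group")
    else:
        conditions = [scores < q1, scores < q2, scores < q3]
        labels = pd.Series(np.select(conditions, ["Q1", "Q2", "Q3"], default="Q4"),
                           index=scores.index, name="risk_group")
    return RiskGroups(q1=float(q1), q2=float(q2), q3=float(q3),
                      labels=labels, n_groups=n_groups)


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate with right censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if times.size == 0:
        raise DomainError("need at least one observation")
    if (times < 0).any():
        raise DomainError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 and \
        kmf.event_table.iloc[0][["observed", "censored"]].sum() == 0 \
        else kmf.event_table
    t = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()
    return SurvivalCurve(
        times=t,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        events=table["observed"].to_numpy(dtype=int),
        censored=table["censored"].to_numpy(dtype=int),
        survival=surv,
    )


def logrank_test(times, events, group_labels) -> LogRankResult:
    """Log-rank chi-square test across two or more groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = pd.Series(group_labels).astype(str).to_numpy()
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise DomainError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(times, groups, events)
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        stat = 0.0
    return LogRankResult(statistic=stat, df=int(uniq.size - 1),
                         p_value=float(res.p_value) if np.isfinite(res.p_value)
                         else 1.0)
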