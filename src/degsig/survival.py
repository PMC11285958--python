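"""Kaplan-Meier estimation and k-group log-rank testing.

Implements the product-limit estimator and the standard log-rank
chi-square test (hypergeometric variance, k-group generalization) with
full observed/expected tabulation, plus the pipeline's two-group and
combined four-group stratified survival comparisons.  Ties follow the
usual convention: events are processed before censorings at equal times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import DegsigError, logger
from .io import ClinicalTable
from .stratify import FOUR_GROUPS, StratifyResult, four_group_assign


@dataclass
class KmCurve:
    """Product-limit estimate over the distinct event times of one group."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    censored: np.ndarray  # censorings in [t_i, t_{i+1})
    survival: np.ndarray  # S(t_i)
    label: str = ""

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S = 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median_survival(self) -> float:
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "at_risk": self.at_risk, "events": self.events,
             "censored": self.censored, "survival": self.survival}
        )


@dataclass
class LogRankResult:
    chi2: float
    df: int
    p: float
    observed: np.ndarray  # per-group observed events
    expected: np.ndarray  # per-group expected events
    group_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.group_labels, "observed": self.observed,
                             "expected": self.expected})


def km_estimate(times, events, label: str = "") -> KmCurve:
    """Kaplan-Meier product-limit estimator."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.shape != e.shape or t.size < 1:
        raise DegsigError("times and events must be equal-length, non-empty")
    if (t <= 0).any():
        raise DegsigError("survival times must be positive")
    event_times = np.unique(t[e == 1])
    n = t.size
    at_risk, d_i, c_i, surv = [], [], [], []
    s = 1.0
    for i, et in enumerate(event_times):
        r = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        upper = event_times[i + 1] if i + 1 < event_times.size else np.inf
        c = int(((t >= et) & (t < upper) & (e == 0)).sum())
        s *= 1.0 - d / r
        at_risk.append(r)
        d_i.append(d)
        c_i.append(c)
        surv.append(s)
    return KmCurve(
        times=event_times, at_risk=np.array(at_risk, dtype=int),
        events=np.array(d_i, dtype=int), censored=np.array(c_i, dtype=int),
        survival=np.array(surv), label=label,
    )


def logrank(groups: list[tuple], labels: list[str] | None = None) -> LogRankResult:
    """k-group log-rank test; each group is a (times, events) pair.

    At each distinct event time the expected events per group are the
    at-risk share of the total events; the chi-square uses the
    multivariate hypergeometric covariance over the first k-1 groups.
    """
    k = len(groups)
    if k < 2:
        raise DegsigError("log-rank needs >= 2 groups")
    labels = labels or [f"group{i}" for i in range(k)]
    ts = [np.asarray(t, dtype=float) for t, _ in groups]
    es = [np.asarray(e, dtype=int) for _, e in groups]
    for t, e in zip(ts, es):
        if t.size < 1 or t.shape != e.shape:
            raise DegsigError("each group needs >= 1 subject with matching events")
        if (t <= 0).any():
            raise DegsigError("survival times must be positive")
    all_t = np.concatenate(ts)
    all_e = np.concatenate(es)
    event_times = np.unique(all_t[all_e == 1])
    if event_times.size == 0:
        raise DegsigError("no events in any group")

    observed = np.zeros(k)
    expected = np.zeros(k)
    V = np.zeros((k - 1, k - 1))
    oe = np.zeros(k - 1)
    for et in event_times:
        n_j = np.array([float((t >= et).sum()) for t in ts])
        d_j = np.array([float(((t == et) & (e == 1)).sum()) for t, e in zip(ts, es)])
        N = n_j.sum()
        D = d_j.sum()
        e_j = D * n_j / N
        observed += d_j
        expected += e_j
        if N > 1:
            frac = n_j[: k - 1] / N
            cov = (D * (N - D) / (N - 1)) * (np.diag(frac) - np.outer(frac, frac))
            V += cov
        oe += d_j[: k - 1] - e_j[: k - 1]
    chi2 = float(oe @ np.linalg.pinv(V) @ oe)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return LogRankResult(chi2=chi2, df=df, p=p, observed=observed, expected=expected,
                         group_labels=list(labels))


def _clin_arrays(clin: ClinicalTable, sample_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    present = [s for s in sample_ids if s in set(clin.sample_ids)]
    sub = clin.data.loc[present]
    return sub["os_time"].to_numpy(dtype=float), sub["os_event"].to_numpy(dtype=int)


def survival_by_stratification(strat: StratifyResult, clin: ClinicalTable) -> tuple[KmCurve, KmCurve, LogRankResult]:
    """Two-group KM + log-rank comparison of a high/low stratification."""
    t_hi, e_hi = _clin_arrays(clin, strat.high_ids)
    t_lo, e_lo = _clin_arrays(clin, strat.low_ids)
    if t_hi.size < 2 or t_lo.size < 2:
        raise DegsigError(f"each stratified group needs >= 2 clinical records, got {t_hi.size}/{t_lo.size}")
    km_hi = km_estimate(t_hi, e_hi, label="high")
    km_lo = km_estimate(t_lo, e_lo, label="low")
    lr = logrank([(t_hi, e_hi), (t_lo, e_lo)], labels=["high", "low"])
    logger.info("two-group log-rank: chi2=%.4g p=%.4g (n=%d/%d)", lr.chi2, lr.p, t_hi.size, t_lo.size)
    return km_hi, km_lo, lr


def combined_survival(
    strat_gene: StratifyResult, strat_signature: StratifyResult, clin: ClinicalTable
) -> tuple[dict[str, KmCurve], LogRankResult, dict[tuple[str, str], LogRankResult]]:
    """Four-group (HH/HL/LH/LL) KM curves, overall and pairwise log-rank.

    Pairwise p-values are reported raw (no multiplicity correction), one
    per unordered group pair.
    """
    assignment = four_group_assign(strat_gene, strat_signature)
    clin_ids = set(clin.sample_ids)
    group_ids = {g: [s for s, grp in assignment.items() if grp == g and s in clin_ids] for g in FOUR_GROUPS}
    short = [g for g, ids in group_ids.items() if len(ids) < 2]
    if short:
        raise DegsigError(f"four-group survival: groups with < 2 clinical records: {short}")
    data = {g: _clin_arrays(clin, ids) for g, ids in group_ids.items()}
    curves = {g: km_estimate(t, e, label=g) for g, (t, e) in data.items()}
    overall = logrank([data[g] for g in FOUR_GROUPS], labels=list(FOUR_GROUPS))
    pairwise: dict[tuple[str, str], LogRankResult] = {}
    for i, g1 in enumerate(FOUR_GROUPS):
        for g2 in FOUR_GROUPS[i + 1:]:
            pairwise[(g1, g2)] = logrank([data[g1], data[g2]], labels=[g1, g2])
    logger.info("four-group log-rank: chi2=%.4g df=%d p=%.4g", overall.chi2, overall.df, overall.p)
    return curves, overall, pairwise
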