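"""Kaplan–Meier estimation and two-group survival tests.

The screen's default comparison is a two-sided Wilcoxon rank-sum test on the
observed follow-up times (censoring flags ignored); the censoring-aware
log-rank and Gehan–Wilcoxon tests are available through the same interface
and are always printed alongside in per-biomarker reports.

Conventions: deaths are processed before censorings tied at the same time;
the median is the smallest observed time with S(t) <= 0.5 and is undefined
(None) when S never reaches 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class KMCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct event times, ``survival`` the estimate just
    after each, ``at_risk`` the risk-set size just before each.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray
    n: int
    median: float | None

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function starting at 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalTestResult:
    statistic: float
    p_value: float
    test_name: str
    n_per_group: tuple[int, int]
    degenerate: bool = False


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator S(t) = prod_{t_i<=t} (1 - d_i/n_i)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("negative survival times")
    n = t.size
    event_times = np.unique(t[e == 1])
    surv = []
    at_risk = []
    s = 1.0
    for et in event_times:
        n_i = int(np.sum(t >= et))  # deaths precede censorings at ties
        d_i = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        surv.append(s)
    surv_arr = np.asarray(surv)
    median = None
    reached = np.nonzero(surv_arr <= 0.5)[0]
    if reached.size:
        median = float(event_times[reached[0]])
    return KMCurve(
        times=event_times,
        survival=surv_arr,
        at_risk=np.asarray(at_risk, dtype=int),
        censor_times=np.sort(t[e == 0]),
        n=n,
        median=median,
    )


def _weighted_logrank(tA, eA, tB, eB, weight: str) -> tuple[float, float, bool]:
    """(chi-square statistic, p, degenerate) for weight in {'logrank', 'gehan'}.

    Observed-minus-expected events in group A aggregated over the distinct
    event times of the pooled sample, with the hypergeometric variance; the
    Gehan variant weights each time by the pooled number at risk.
    """
    t = np.concatenate([tA, tB])
    e = np.concatenate([eA, eB]).astype(bool)
    in_a = np.concatenate([np.ones(len(tA), dtype=bool), np.zeros(len(tB), dtype=bool)])
    event_times = np.unique(t[e])
    if event_times.size == 0:
        return 0.0, 1.0, True
    t_sorted = np.sort(t)
    ta_sorted = np.sort(t[in_a])
    n_i = t.size - np.searchsorted(t_sorted, event_times, side="left")
    n_a = in_a.sum() - np.searchsorted(ta_sorted, event_times, side="left")
    te_sorted = np.sort(t[e])
    d_i = np.searchsorted(te_sorted, event_times, side="right") - np.searchsorted(
        te_sorted, event_times, side="left"
    )
    tea_sorted = np.sort(t[e & in_a])
    d_a = np.searchsorted(tea_sorted, event_times, side="right") - np.searchsorted(
        tea_sorted, event_times, side="left"
    )
    ok = n_i >= 2
    n_i, n_a, d_i, d_a = n_i[ok], n_a[ok], d_i[ok], d_a[ok]
    if n_i.size == 0:
        return 0.0, 1.0, True
    frac = n_a / n_i
    w = n_i.astype(float) if weight == "gehan" else np.ones_like(frac)
    num = float(np.sum(w * (d_a - d_i * frac)))
    var = float(np.sum(w * w * d_i * frac * (1 - frac) * (n_i - d_i) / (n_i - 1)))
    if var == 0:
        return 0.0, 1.0, True
    chi2 = num * num / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p, False


def logrank_test(times_a, events_a, times_b, events_b) -> SurvivalTestResult:
    """Two-sided one-degree-of-freedom log-rank test."""
    tA, eA = np.asarray(times_a, float), np.asarray(events_a, int)
    tB, eB = np.asarray(times_b, float), np.asarray(events_b, int)
    if tA.size == 0 or tB.size == 0:
        raise ValueError("both groups must be non-empty")
    chi2, p, degen = _weighted_logrank(tA, eA, tB, eB, "logrank")
    return SurvivalTestResult(chi2, p, "logrank", (tA.size, tB.size), degen)


def gehan_wilcoxon_test(times_a, events_a, times_b, events_b) -> SurvivalTestResult:
    """Gehan–Wilcoxon (Breslow) test: log-rank weighted by the number at risk.

    Emphasizes early events; the censoring-aware analogue of the rank-sum
    test offered because the screen's rank-sum comparison ignores censoring.
    """
    tA, eA = np.asarray(times_a, float), np.asarray(events_a, int)
    tB, eB = np.asarray(times_b, float), np.asarray(events_b, int)
    if tA.size == 0 or tB.size == 0:
        raise ValueError("both groups must be non-empty")
    chi2, p, degen = _weighted_logrank(tA, eA, tB, eB, "gehan")
    return SurvivalTestResult(chi2, p, "gehan", (tA.size, tB.size), degen)


EXACT_MAX_N = 12


def ranksum_test(values_a, values_b) -> SurvivalTestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact p by enumeration when nA + nB <= 12 with no ties; otherwise the
    normal approximation with tie-corrected variance and continuity
    correction.  Ties receive mid-ranks.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return SurvivalTestResult(0.0, 1.0, "ranksum", (a.size, b.size), degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= EXACT_MAX_N and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return SurvivalTestResult(float(res.statistic), float(res.pvalue), "ranksum", (a.size, b.size))


TESTS = {"ranksum": "ranksum", "logrank": "logrank", "gehan": "gehan"}


def survival_test(times_a, events_a, times_b, events_b, test: str = "ranksum") -> SurvivalTestResult:
    """Dispatch on test name; rank-sum uses observed times ignoring events."""
    if test == "ranksum":
        return ranksum_test(times_a, times_b)
    if test == "logrank":
        return logrank_test(times_a, events_a, times_b, events_b)
    if test == "gehan":
        return gehan_wilcoxon_test(times_a, events_a, times_b, events_b)
    raise ValueError(f"unknown survival test {test!r}")
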