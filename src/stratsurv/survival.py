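"""Kaplan-Meier estimation, two-group weighted log-rank tests and
univariate Cox proportional-hazards fitting, from first principles.

Conventions: events at a given time are processed before censorings at the
same time; the Mantel-Haenszel test uses unit weights and the
Gehan-Wilcoxon variant weights each event time by the number at risk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "km_estimate",
    "risk_table",
    "logrank_test",
    "cox_univariate",
]


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not (self.time > 0 and math.isfinite(self.time)):
            raise ValueError(f"time must be positive and finite, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival after each distinct event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    n_total: int
    all_times: np.ndarray = field(repr=False, default=None)

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function starting at 1."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


@dataclass(frozen=True)
class LogRankResult:
    observed: tuple[float, float]
    expected: tuple[float, float]
    variance: float
    statistic: float
    p_value: float
    weighting: str
    degenerate: bool = False


@dataclass(frozen=True)
class CoxFit:
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    separation: bool = False
    n_iter: int = 0


def _times_events(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=int)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimator over distinct event times."""
    if len(records) == 0:
        raise ValueError("km_estimate needs at least one record")
    t, e = _times_events(records)
    n = t.size
    event_times = np.unique(t[e == 1])

    surv = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    d_counts = np.empty(event_times.size, dtype=int)
    s = 1.0
    for i, et in enumerate(event_times):
        nr = int(np.count_nonzero(t >= et))  # censored at et still at risk
        d = int(np.count_nonzero((t == et) & (e == 1)))
        s *= 1.0 - d / nr
        surv[i] = s
        at_risk[i] = nr
        d_counts[i] = d
    return KMCurve(event_times=event_times, survival=surv, at_risk=at_risk,
                   events=d_counts, n_total=n, all_times=np.sort(t))


def risk_table(curve: KMCurve, times: Iterable[float]) -> list[int]:
    """Number at risk immediately before each requested time."""
    out = []
    for t in times:
        if t < 0:
            raise ValueError("times must be non-negative")
        out.append(int(np.count_nonzero(curve.all_times >= t)))
    return out


def _logrank_arrays(
    t1: np.ndarray, e1: np.ndarray, t2: np.ndarray, e2: np.ndarray,
    weighting: str,
) -> LogRankResult:
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    g = np.concatenate([np.zeros(t1.size, bool), np.ones(t2.size, bool)])

    total_events = int(e.sum())
    if total_events == 0:
        return LogRankResult((0.0, 0.0), (0.0, 0.0), 0.0, 0.0, 1.0,
                             weighting, degenerate=True)

    event_times = np.unique(t[e == 1])
    o1 = e1.sum()
    num = 0.0  # sum w (O1 - E1)
    var = 0.0  # sum w^2 V
    e1_sum = 0.0
    for et in event_times:
        at = t >= et
        n_r = int(at.sum())
        n1 = int((at & ~g).sum())
        d = int(((t == et) & (e == 1)).sum())
        exp1 = d * n1 / n_r
        e1_sum += exp1
        d1 = int(((t1 == et) & (e1 == 1)).sum())
        v = 0.0
        if n_r > 1:
            v = d * (n1 / n_r) * (1 - n1 / n_r) * (n_r - d) / (n_r - 1)
        w = float(n_r) if weighting == "gehan-wilcoxon" else 1.0
        num += w * (d1 - exp1)
        var += w * w * v

    o2 = float(e2.sum())
    e2_sum = total_events - e1_sum
    if var <= 0.0:
        return LogRankResult((float(o1), o2), (e1_sum, e2_sum), var, 0.0, 1.0,
                             weighting, degenerate=True)
    chi2 = num * num / var
    p = float(_sps.chi2.sf(chi2, 1))
    return LogRankResult((float(o1), o2), (e1_sum, e2_sum), var, chi2, p, weighting)


def logrank_test(
    group1: Sequence[SurvivalRecord],
    group2: Sequence[SurvivalRecord],
    weighting: Literal["mantel-haenszel", "gehan-wilcoxon"] = "mantel-haenszel",
) -> LogRankResult:
    """Two-group weighted log-rank test.

    ``mantel-haenszel`` uses unit weights; ``gehan-wilcoxon`` weights each
    event time by the total number at risk. The chi-square statistic is
    (sum w (O - E))^2 / sum w^2 V with the hypergeometric variance at each
    distinct event time; p from chi-square with 1 df. With no events the
    result is degenerate with p = 1.
    """
    if weighting not in ("mantel-haenszel", "gehan-wilcoxon"):
        raise ValueError(f"unknown weighting: {weighting}")
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("both groups must be non-empty")
    t1, e1 = _times_events(group1)
    t2, e2 = _times_events(group2)
    return _logrank_arrays(t1, e1, t2, e2, weighting)


def logrank_fast(
    times: np.ndarray, events: np.ndarray, in_group2: np.ndarray,
    weighting: str = "mantel-haenszel",
) -> tuple[float, float]:
    """Array-based log-rank returning (chi-square, p); used in tight loops
    (cutpoint search, permutation nulls). Same definition as logrank_test."""
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    g2 = np.asarray(in_group2, bool)
    if e.sum() == 0:
        return 0.0, 1.0

    order = np.argsort(t, kind="stable")
    t, e, g2 = t[order], e[order], g2[order]
    n = t.size

    event_mask = e == 1
    event_times, first_idx = np.unique(t[event_mask], return_index=True)
    # counts at each distinct event time
    d = np.zeros(event_times.size)
    d1 = np.zeros(event_times.size)
    idx = np.searchsorted(event_times, t[event_mask])
    np.add.at(d, idx, 1.0)
    np.add.at(d1, idx, (~g2[event_mask]).astype(float))
    # at-risk counts: everyone with time >= event time
    n_r = n - np.searchsorted(t, event_times, side="left")
    cum_g1 = np.cumsum(~g2)
    before = np.searchsorted(t, event_times, side="left")
    total_g1 = cum_g1[-1]
    n1 = total_g1 - np.where(before > 0, cum_g1[before - 1], 0)

    exp1 = d * n1 / n_r
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(n_r > 1,
                     d * (n1 / n_r) * (1 - n1 / n_r) * (n_r - d) / np.maximum(n_r - 1, 1),
                     0.0)
    w = n_r.astype(float) if weighting == "gehan-wilcoxon" else np.ones_like(exp1)
    num = float((w * (d1 - exp1)).sum())
    var = float((w * w * v).sum())
    if var <= 0.0:
        return 0.0, 1.0
    chi2 = num * num / var
    return chi2, float(_sps.chi2.sf(chi2, 1))


def logrank_grid(
    times: np.ndarray, events: np.ndarray, hi_masks: np.ndarray,
    weighting: str = "mantel-haenszel",
) -> np.ndarray:
    """Log-rank chi-square for many group assignments at once.

    ``hi_masks`` is a (K, n) boolean array; row k defines group 2 of the
    k-th candidate split. Returns the K chi-square statistics (0 where the
    variance degenerates). Shares its definition with :func:`logrank_test`;
    used by the cutpoint search and its permutation null.
    """
    t = np.asarray(times, float)
    e = np.asarray(events, int)
    masks = np.atleast_2d(np.asarray(hi_masks, bool))
    if e.sum() == 0:
        return np.zeros(masks.shape[0])

    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    g1 = ~masks[:, order]  # (K, n) membership in group 1
    n = t.size

    ev = e == 1
    event_times = np.unique(t[ev])
    m = event_times.size
    idx = np.searchsorted(event_times, t[ev])
    d = np.zeros(m)
    np.add.at(d, idx, 1.0)
    before = np.searchsorted(t, event_times, side="left")
    n_r = (n - before).astype(float)

    cum_g1 = np.cumsum(g1, axis=1)  # (K, n)
    total_g1 = cum_g1[:, -1:]
    n1 = total_g1 - np.where(before > 0, cum_g1[:, np.maximum(before - 1, 0)], 0.0)
    # observed group-1 events per distinct event time, per mask
    g1_ev = g1[:, ev].astype(float)  # (K, n_events) ordered by time
    starts = np.searchsorted(idx, np.arange(m))
    d1 = np.add.reduceat(g1_ev, starts, axis=1)

    frac = n1 / n_r
    exp1 = d * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(n_r > 1,
                     d * frac * (1 - frac) * (n_r - d) / np.maximum(n_r - 1, 1.0),
                     0.0)
    w = n_r if weighting == "gehan-wilcoxon" else np.ones(m)
    num = ((d1 - exp1) * w).sum(axis=1)
    var = (v * w * w).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, num * num / var, 0.0)
    return chi2


def _cox_loglik(beta: float, t: np.ndarray, e: np.ndarray, x: np.ndarray):
    """Breslow partial log-likelihood with first two derivatives."""
    order = np.argsort(-t, kind="stable")  # decreasing time
    t_s, e_s, x_s = t[order], e[order], x[order]
    eta = beta * x_s
    r = np.exp(eta)
    # cumulative sums over the risk set (times >= current)
    s0 = np.cumsum(r)
    s1 = np.cumsum(r * x_s)
    s2 = np.cumsum(r * x_s * x_s)

    ll = 0.0
    score = 0.0
    info = 0.0
    i = 0
    n = t_s.size
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # risk set for this time includes all of positions [0, j)
        d_idx = [k for k in range(i, j) if e_s[k] == 1]
        if d_idx:
            d = len(d_idx)
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            xs = x_s[d_idx].sum()
            ll += beta * xs - d * math.log(S0)
            score += xs - d * S1 / S0
            info += d * (S2 / S0 - (S1 / S0) ** 2)
        i = j
    return ll, score, info


def cox_univariate(
    covariate: Sequence[float],
    records: Sequence[SurvivalRecord],
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Univariate Cox proportional-hazards fit (Breslow tie handling).

    Newton-Raphson from beta = 0 on the partial likelihood; SE from the
    observed information; Wald p and 95% CI. Monotone likelihood
    (separation) is flagged and yields no CI.
    """
    x = np.asarray(covariate, dtype=float)
    t, e = _times_events(records)
    if x.size != t.size:
        raise ValueError("covariate and records must align")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    if e.sum() == 0:
        raise ValueError("at least one event required")

    beta = 0.0
    converged = False
    separation = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, score, info = _cox_loglik(beta, t, e, x)
        if info <= 1e-12:
            separation = True
            break
        step = score / info
        # dampen wild steps
        if abs(step) > 5.0:
            step = math.copysign(5.0, step)
        beta += step
        if abs(beta) > 50.0:
            separation = True
            break
        if abs(step) < tol:
            converged = True
            break

    if separation or not converged:
        _, _, info = _cox_loglik(beta, t, e, x)
        se = math.inf if info <= 1e-12 else 1.0 / math.sqrt(info)
        return CoxFit(beta=beta, se=se, hr=math.exp(beta),
                      ci_low=math.nan, ci_high=math.nan, p_value=math.nan,
                      converged=converged, separation=True, n_iter=it)

    _, _, info = _cox_loglik(beta, t, e, x)
    se = 1.0 / math.sqrt(info)
    z = beta / se
    p = 2.0 * _sps.norm.sf(abs(z))
    zc = _sps.norm.ppf(0.975)
    return CoxFit(beta=beta, se=se, hr=math.exp(beta),
                  ci_low=math.exp(beta - zc * se), ci_high=math.exp(beta + zc * se),
                  p_value=min(p, 1.0), converged=True, n_iter=it)


def cox_score_test(covariate: Sequence[float],
                   records: Sequence[SurvivalRecord]) -> tuple[float, float]:
    """Score (Rao) test at beta = 0: chi-square = score^2 / information.

    With a binary covariate and Breslow ties this equals the
    Mantel-Haenszel log-rank chi-square.
    """
    x = np.asarray(covariate, dtype=float)
    t, e = _times_events(records)
    _, score, info = _cox_loglik(0.0, t, e, x)
    if info <= 0:
        return 0.0, 1.0
    chi2 = score * score / info
    return chi2, float(_sps.chi2.sf(chi2, 1))
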