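"""Elementary statistical tests and scores used throughout the package.

Implements two-sample t tests (pooled and Welch), the Mann-Whitney U test
with exact small-sample enumeration, one- and two-way ANOVA, Benjamini-
Hochberg FDR adjustment, the hypergeometric enrichment test with its
conservative EASE variant, and the immunohistochemistry H-score.

Test statistics are computed from first principles; reference distributions
(t, F, chi-square, hypergeometric) come from :mod:`scipy.stats`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "IHCScore",
    "EnrichmentInputs",
    "EnrichmentResult",
    "ihc_score",
    "t_test_two_tailed",
    "mann_whitney_u",
    "one_way_anova",
    "two_way_anova",
    "bh_adjust",
    "fisher_enrichment",
    "boxplot_summary",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (t, U, F or chi-square depending on ``method``).
    p_value : float
        Two-tailed (or upper-tail, for F / enrichment) p-value in [0, 1].
    df : float | tuple | None
        Degrees of freedom, or ``None`` for exact/nonparametric methods.
    method : str
        Short label identifying the procedure.
    degenerate : bool
        True when the input admitted no variability and the result is a
        convention rather than a computed tail probability.
    """

    statistic: float
    p_value: float
    df: object = None
    method: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class IHCScore:
    """Immunohistochemistry H-score: percent positive cells x intensity."""

    percent_positive: float
    intensity: int
    score: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_positive <= 100.0:
            raise ValueError(
                f"percent_positive must be in [0, 100], got {self.percent_positive}"
            )
        if self.intensity not in (0, 1, 2, 3):
            raise ValueError(f"intensity must be in {{0,1,2,3}}, got {self.intensity}")
        object.__setattr__(self, "score", self.percent_positive * self.intensity)


def ihc_score(percent_positive: float, intensity: int) -> IHCScore:
    """Score a stained core by multiplying percent positive cells (0-100)
    with staining intensity (0 = none, 1 = weak, 2 = medium, 3 = strong)."""
    return IHCScore(percent_positive=float(percent_positive), intensity=int(intensity))


@dataclass(frozen=True)
class EnrichmentInputs:
    """2x2 margins for an over-representation test.

    ``universe_size`` (N) genes total, of which ``term_size`` (K) belong to
    the term; a query list of ``list_size`` (n) genes overlaps the term in
    ``overlap`` (k) genes.
    """

    universe_size: int
    term_size: int
    list_size: int
    overlap: int

    def __post_init__(self) -> None:
        N, K, n, k = self.universe_size, self.term_size, self.list_size, self.overlap
        if n <= 0:
            raise ValueError("list_size must be positive")
        if not (0 <= K <= N):
            raise ValueError(f"term_size must satisfy 0 <= K <= N, got K={K}, N={N}")
        if not (0 < n <= N):
            raise ValueError(f"list_size must satisfy 0 < n <= N, got n={n}, N={N}")
        if not (0 <= k <= min(K, n)):
            raise ValueError(f"overlap must satisfy 0 <= k <= min(K, n), got k={k}")


@dataclass(frozen=True)
class EnrichmentResult:
    test: TestResult
    fold_enrichment: float


def _as_array(values: Sequence[float], name: str, min_len: int = 1) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size < min_len:
        raise ValueError(f"{name} needs at least {min_len} values, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def t_test_two_tailed(
    group_a: Sequence[float],
    group_b: Sequence[float],
    equal_variance: bool = False,
) -> TestResult:
    """Two-sample two-tailed t test.

    By default uses the Welch statistic with Satterthwaite degrees of
    freedom; ``equal_variance=True`` gives the pooled-variance Student test.
    The sign of the statistic follows ``mean(a) - mean(b)``.
    """
    a = _as_array(group_a, "group_a", min_len=2)
    b = _as_array(group_b, "group_b", min_len=2)
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = ma - mb

    if va == 0.0 and vb == 0.0:
        # No variability at all: decided by the means alone.
        if diff == 0.0:
            return TestResult(0.0, 1.0, None, "t-test", degenerate=True)
        return TestResult(math.copysign(math.inf, diff), 0.0, None, "t-test",
                          degenerate=True)

    if equal_variance:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        df: float = na + nb - 2
        method = "t-test (pooled)"
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        method = "t-test (Welch)"

    t = diff / se
    p = 2.0 * _sps.t.sf(abs(t), df)
    return TestResult(t, min(p, 1.0), df, method)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a: #(a_i > b_j) + 0.5 #(a_i == b_j)."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_mwu_p(na: int, nb: int, u_obs: float) -> float:
    """Exact two-sided p by enumerating all C(na+nb, na) rank assignments.

    Doubling convention: p = min(1, 2 * min(P(U <= u), P(U >= u))).
    Only valid without ties (ranks 1..na+nb distinct).
    """
    n = na + nb
    ranks = np.arange(1, n + 1)
    # U = R_a - na(na+1)/2 for untied data
    offset = na * (na + 1) / 2.0
    us = []
    for combo in itertools.combinations(range(n), na):
        us.append(ranks[list(combo)].sum() - offset)
    us_arr = np.array(us)
    total = us_arr.size
    lo = np.count_nonzero(us_arr <= u_obs + 1e-9) / total
    hi = np.count_nonzero(us_arr >= u_obs - 1e-9) / total
    return min(1.0, 2.0 * min(lo, hi))


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    method: str = "auto",
) -> TestResult:
    """Two-sided Mann-Whitney U test; U is reported for ``group_a``.

    ``method="auto"`` uses exact enumeration when ``n_a + n_b <= 12`` and
    the pooled sample has no ties, otherwise the continuity-corrected
    normal approximation with tie correction; ``"exact"``/``"normal"``
    force one branch.
    """
    a = _as_array(group_a, "group_a")
    b = _as_array(group_b, "group_b")
    na, nb = a.size, b.size
    u = _u_statistic(a, b)

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if method not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown method: {method}")
    use_exact = (method == "exact"
                 or (method == "auto" and na + nb <= 12 and not has_ties))
    if use_exact:
        if has_ties:
            raise ValueError("exact enumeration requires untied data")
        p = _exact_mwu_p(na, nb, u)
        return TestResult(u, p, None, "mann-whitney (exact)")

    mu = na * nb / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    n = na + nb
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var <= 0.0:
        return TestResult(u, 1.0, None, "mann-whitney (normal)", degenerate=True)
    z = max(abs(u - mu) - 0.5, 0.0) / math.sqrt(var)  # continuity correction
    p = 2.0 * _sps.norm.sf(z)
    return TestResult(u, min(p, 1.0), None, "mann-whitney (normal)")


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA; F = MS_between / MS_within."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [_as_array(g, f"group {i}", min_len=2) for i, g in enumerate(groups)]
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    k = len(arrays)
    n = all_vals.size

    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_b, df_w = k - 1, n - k

    if ssw == 0.0:
        if ssb == 0.0:
            return TestResult(0.0, 1.0, (df_b, df_w), "anova", degenerate=True)
        return TestResult(math.inf, 0.0, (df_b, df_w), "anova", degenerate=True)

    f = (ssb / df_b) / (ssw / df_w)
    p = _sps.f.sf(f, df_b, df_w)
    return TestResult(f, float(p), (df_b, df_w), "anova")


def _dummy_matrix(levels: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    return (codes[:, None] == np.arange(1, levels.size)[None, :]).astype(float)


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence[object],
    factor_b: Sequence[object],
) -> dict[str, TestResult]:
    """Main-effect F tests for a two-factor layout (type-II sums of squares).

    Fits the additive model; each factor's sum of squares is its reduction
    in residual SS given the other factor. A factor with a single level
    contributes no columns: the other factor's test then reduces to the
    one-way ANOVA and the single-level factor is reported as degenerate.
    """
    y = _as_array(values, "values")
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if fa.size != y.size or fb.size != y.size:
        raise ValueError("values and factors must have equal length")

    lev_a, codes_a = np.unique(fa, return_inverse=True)
    lev_b, codes_b = np.unique(fb, return_inverse=True)
    if lev_a.size < 2 and lev_b.size < 2:
        raise ValueError("each factor needs at least two levels")

    intercept = np.ones((y.size, 1))
    Xa = _dummy_matrix(lev_a, codes_a)
    Xb = _dummy_matrix(lev_b, codes_b)

    rss_full = _rss(y, np.hstack([intercept, Xa, Xb]))
    df_resid = y.size - 1 - (lev_a.size - 1) - (lev_b.size - 1)
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom in additive model")
    ms_resid = rss_full / df_resid

    out: dict[str, TestResult] = {}
    for name, X_other, df_eff in (
        ("factor_a", Xb, lev_a.size - 1),
        ("factor_b", Xa, lev_b.size - 1),
    ):
        if df_eff == 0:
            out[name] = TestResult(float("nan"), 1.0, (0, df_resid),
                                   "two-way anova", degenerate=True)
            continue
        rss_reduced = _rss(y, np.hstack([intercept, X_other]))
        ss_eff = rss_reduced - rss_full
        if ms_resid == 0.0:
            out[name] = TestResult(math.inf if ss_eff > 0 else 0.0,
                                   0.0 if ss_eff > 0 else 1.0,
                                   (df_eff, df_resid), "two-way anova",
                                   degenerate=True)
            continue
        f = (ss_eff / df_eff) / ms_resid
        f = max(f, 0.0)
        out[name] = TestResult(f, float(_sps.f.sf(f, df_eff, df_resid)),
                               (df_eff, df_resid), "two-way anova")
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (returns values in input order).

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0.0) | (p > 1.0)) or not np.all(np.isfinite(p)):
        raise ValueError("p_values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def fisher_enrichment(inputs: EnrichmentInputs, ease: bool = True) -> EnrichmentResult:
    """One-tailed over-representation test on hypergeometric margins.

    With ``ease=False`` the classical Fisher upper tail P(X >= k); with
    ``ease=True`` the conservative EASE score P(X >= k - 1) obtained by
    discounting one overlapping gene (k <= 1 gives p = 1).
    """
    N, K, n, k = (inputs.universe_size, inputs.term_size,
                  inputs.list_size, inputs.overlap)
    if ease:
        p = 1.0 if k <= 1 else float(_sps.hypergeom.sf(k - 2, N, K, n))
        method = "ease"
    else:
        p = float(_sps.hypergeom.sf(k - 1, N, K, n))
        method = "fisher"
    p = min(max(p, 0.0), 1.0)
    fold = (k / n) / (K / N) if K > 0 else math.nan
    return EnrichmentResult(
        test=TestResult(float(k), p, None, method),
        fold_enrichment=fold,
    )


def boxplot_summary(values: Sequence[float]) -> dict[str, float]:
    """Descriptive summary matching the plotting convention: median with
    IQR box and whiskers at median +/- 1.5 * IQR."""
    v = _as_array(values, "values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(med - 1.5 * iqr),
        "whisker_high": float(med + 1.5 * iqr),
    }
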