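"""Maximally selected survival cutpoint for a single index gene.

Candidate thresholds are the midpoints between consecutive distinct
expression values; the threshold maximizing the Mantel-Haenszel chi-square
between the resulting lo/hi groups is selected. Because the maximum is
taken over many correlated tests, the unadjusted p at the optimum is
anti-conservative; an optional permutation correction re-runs the full
search on label-permuted survival data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scipy import stats as _sps

from .survival import LogRankResult, SurvivalRecord, logrank_grid, logrank_test

__all__ = [
    "CutpointResult",
    "candidate_thresholds",
    "find_optimal_cutpoint",
    "selection_adjusted_p",
]


@dataclass(frozen=True)
class CutpointResult:
    optimal_threshold: float
    candidate_table: pd.DataFrame  # columns: threshold, statistic, p_value, n_lo, n_hi
    labels: dict[str, str]  # sample_id -> "lo" | "hi"
    n_lo: int
    n_hi: int
    test: LogRankResult
    adjusted_p: float | None = None
    sample_ids: tuple[str, ...] = field(default=(), repr=False)

    def label_for(self, expression_value: float) -> str:
        """Label a new sample from the stored threshold (hi iff strictly above)."""
        return "hi" if expression_value > self.optimal_threshold else "lo"


def candidate_thresholds(
    expression: np.ndarray | list[float],
    min_group_fraction: float = 0.1,
) -> np.ndarray:
    """Midpoints between consecutive distinct sorted expression values,
    restricted so that both resulting groups hold at least
    ``ceil(min_group_fraction * n)`` samples."""
    x = np.asarray(expression, dtype=float)
    if not (0.0 < min_group_fraction < 0.5):
        raise ValueError("min_group_fraction must lie in (0, 0.5)")
    distinct = np.unique(x)
    if distinct.size < 2:
        raise ValueError("need at least two distinct expression values")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = x.size
    min_count = math.ceil(min_group_fraction * n)
    keep = []
    for thr in mids:
        n_hi = int(np.count_nonzero(x > thr))
        if n_hi >= min_count and (n - n_hi) >= min_count:
            keep.append(thr)
    if not keep:
        raise ValueError(
            f"no candidate threshold leaves >= {min_count} samples per group"
        )
    return np.asarray(keep)


def find_optimal_cutpoint(
    expression: dict[str, float] | pd.Series,
    records: list[SurvivalRecord],
    min_group_fraction: float = 0.1,
    weighting: str = "mantel-haenszel",
) -> CutpointResult:
    """Exhaustively evaluate the log-rank test at every candidate threshold
    and return the argmax of the chi-square statistic.

    Ties in the statistic are broken toward the threshold closest to the
    median expression. The full candidate table is retained for audit.
    """
    expr = pd.Series(expression, dtype=float)
    ids = [r.sample_id for r in records]
    missing = [s for s in ids if s not in expr.index]
    if missing:
        raise ValueError(f"samples missing expression values: {missing[:5]}")
    x = expr.loc[ids].to_numpy()
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records])
    if e.sum() == 0:
        raise ValueError("at least one event is required")

    thresholds = candidate_thresholds(x, min_group_fraction)
    hi_masks = x[None, :] > thresholds[:, None]
    stats = logrank_grid(t, e, hi_masks, weighting)
    pvals = _sps.chi2.sf(stats, 1)
    table = pd.DataFrame({
        "threshold": thresholds,
        "statistic": stats,
        "p_value": pvals,
        "n_lo": (~hi_masks).sum(axis=1),
        "n_hi": hi_masks.sum(axis=1),
    })

    best_stat = table["statistic"].max()
    tied = table.index[table["statistic"] == best_stat]
    med = float(np.median(x))
    best_idx = min(tied, key=lambda i: (abs(table.at[i, "threshold"] - med),
                                        table.at[i, "threshold"]))
    thr_opt = float(table.at[best_idx, "threshold"])

    hi_mask = x > thr_opt
    labels = {sid: ("hi" if h else "lo") for sid, h in zip(ids, hi_mask)}
    lo_recs = [r for r, h in zip(records, hi_mask) if not h]
    hi_recs = [r for r, h in zip(records, hi_mask) if h]
    test = logrank_test(lo_recs, hi_recs, weighting=weighting)

    return CutpointResult(
        optimal_threshold=thr_opt,
        candidate_table=table,
        labels=labels,
        n_lo=int((~hi_mask).sum()),
        n_hi=int(hi_mask.sum()),
        test=test,
        sample_ids=tuple(ids),
    )


def selection_adjusted_p(
    result: CutpointResult,
    records: list[SurvivalRecord],
    expression: dict[str, float] | pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
    min_group_fraction: float = 0.1,
) -> float:
    """Permutation p for the maximally selected statistic.

    Shuffles the (time, event) pairs against the expression values,
    re-runs the full threshold search each time, and reports the add-one
    smoothed fraction of permuted maxima at or above the observed maximum.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    expr = pd.Series(expression, dtype=float)
    ids = [r.sample_id for r in records]
    x = expr.loc[ids].to_numpy()
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records])
    thresholds = candidate_thresholds(x, min_group_fraction)
    hi_masks = x[None, :] > thresholds[:, None]

    observed = float(result.candidate_table["statistic"].max())
    rng = np.random.default_rng(seed)
    n = t.size
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        best = float(logrank_grid(t[perm], e[perm], hi_masks).max())
        if best >= observed - 1e-12:
            exceed += 1
    return (exceed + 1) / (n_permutations + 1)
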