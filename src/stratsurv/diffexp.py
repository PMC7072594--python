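"""Stratified differential expression, cross-study intersection and
gene-set over-representation.

Per study: two-tailed t tests of hi vs lo samples per gene, BH adjustment
over all tested genes, and a signed fold-regulation derived from the log2
mean difference d (2^d for d >= 0, -2^(-d) otherwise). A gene is
significant iff p_FDR < alpha AND |fold_regulation| > fold_threshold
(strict inequalities; defaults 0.05 and 1.25). Genes significant in the
same direction in at least ``min_studies`` studies form the shared sets;
direction conflicts are reported, never silently assigned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import EnrichmentInputs, bh_adjust, fisher_enrichment

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_FOLD_THRESHOLD",
    "IntersectionResult",
    "de_per_study",
    "cross_study_intersection",
    "enrich_gene_list",
    "volcano_table",
]

DEFAULT_ALPHA = 0.05
DEFAULT_FOLD_THRESHOLD = 1.25


def _fold_regulation(d: np.ndarray) -> np.ndarray:
    """Signed fold change from a log2 difference: 2^d if d>=0 else -2^-d."""
    return np.where(d >= 0, np.exp2(d), -np.exp2(-d))


def de_per_study(
    expression: pd.DataFrame,
    labels: dict[str, str],
    alpha: float = DEFAULT_ALPHA,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    equal_variance: bool = False,
    exclude_genes: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-gene hi-vs-lo differential expression table.

    ``expression`` is genes x samples (log2); ``labels`` maps sample id to
    "lo"/"hi". The t tests are vectorised over genes but agree exactly with
    :func:`stratsurv.stats.t_test_two_tailed` gene by gene. Returns a frame
    indexed by gene id with columns mean_lo, mean_hi, t, p, p_fdr,
    fold_regulation, direction, significant.
    """
    hi_ids = [s for s, lab in labels.items() if lab == "hi"]
    lo_ids = [s for s, lab in labels.items() if lab == "lo"]
    unknown = set(hi_ids + lo_ids) - set(expression.columns)
    if unknown:
        raise ValueError(f"labelled samples missing from expression: {sorted(unknown)[:5]}")
    if len(hi_ids) < 2 or len(lo_ids) < 2:
        raise ValueError("each group needs at least two samples")

    frame = expression.drop(index=[g for g in exclude_genes
                                   if g in expression.index])
    hi = frame[hi_ids].to_numpy(dtype=float)
    lo = frame[lo_ids].to_numpy(dtype=float)
    n_hi, n_lo = hi.shape[1], lo.shape[1]
    m_hi, m_lo = hi.mean(axis=1), lo.mean(axis=1)
    v_hi, v_lo = hi.var(axis=1, ddof=1), lo.var(axis=1, ddof=1)
    d = m_hi - m_lo

    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_variance:
            sp2 = ((n_hi - 1) * v_hi + (n_lo - 1) * v_lo) / (n_hi + n_lo - 2)
            se = np.sqrt(sp2 * (1.0 / n_hi + 1.0 / n_lo))
            df = np.full_like(d, float(n_hi + n_lo - 2))
        else:
            se = np.sqrt(v_hi / n_hi + v_lo / n_lo)
            df = (v_hi / n_hi + v_lo / n_lo) ** 2 / (
                (v_hi / n_hi) ** 2 / (n_hi - 1) + (v_lo / n_lo) ** 2 / (n_lo - 1)
            )
        t = d / se
    # degenerate genes: no variance in either group
    zero_var = se == 0
    signed_inf = np.where(d > 0, np.inf, np.where(d < 0, -np.inf, 0.0))
    t = np.where(zero_var, signed_inf, t)
    p = np.where(
        zero_var,
        np.where(d == 0, 1.0, 0.0),
        2.0 * _sps.t.sf(np.abs(np.where(zero_var, 0.0, t)),
                        np.where(zero_var, 1.0, df)),
    )
    p = np.minimum(p, 1.0)
    p_fdr = bh_adjust(p)
    fold = _fold_regulation(d)
    significant = (p_fdr < alpha) & (np.abs(fold) > fold_threshold)
    direction = np.where(~significant, "none", np.where(d > 0, "up", "down"))

    return pd.DataFrame(
        {
            "mean_lo": m_lo,
            "mean_hi": m_hi,
            "t": t,
            "p": p,
            "p_fdr": p_fdr,
            "fold_regulation": fold,
            "direction": direction,
            "significant": significant,
        },
        index=frame.index.rename("gene_id"),
    )


@dataclass(frozen=True)
class IntersectionResult:
    shared_up: list[str]
    shared_down: list[str]
    membership: dict[str, dict[str, list[str]]]  # gene -> {"up": studies, "down": studies}
    conflicts: list[str]
    min_studies: int = 2


def cross_study_intersection(
    tables: dict[str, pd.DataFrame],
    min_studies: int = 2,
) -> IntersectionResult:
    """Genes significantly regulated in the same direction in at least
    ``min_studies`` studies; genes qualifying in both directions are
    reported as conflicts only."""
    if len(tables) < 2:
        raise ValueError("need at least two DE tables")
    shared_namespace = set()
    names = list(tables)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            shared_namespace |= set(tables[a].index) & set(tables[b].index)
    if not shared_namespace:
        warnings.warn("DE tables share no gene identifiers; empty intersection")
        return IntersectionResult([], [], {}, [], min_studies)

    membership: dict[str, dict[str, list[str]]] = {}
    for study, tab in tables.items():
        sig = tab[tab["significant"]]
        for gene, direction in zip(sig.index, sig["direction"]):
            membership.setdefault(gene, {"up": [], "down": []})[direction].append(study)

    up, down, conflicts = [], [], []
    for gene, m in membership.items():
        qual_up = len(m["up"]) >= min_studies
        qual_down = len(m["down"]) >= min_studies
        if qual_up and qual_down:
            conflicts.append(gene)
        elif qual_up:
            up.append(gene)
        elif qual_down:
            down.append(gene)
    return IntersectionResult(sorted(up), sorted(down), membership,
                              sorted(conflicts), min_studies)


def enrich_gene_list(
    gene_list: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    alpha: float = DEFAULT_ALPHA,
    ease: bool = True,
) -> pd.DataFrame:
    """Over-representation of ``gene_list`` in each gene set.

    Counts are taken within ``universe`` (which must contain the list);
    rows are ranked by p (EASE by default), ties broken by descending fold
    enrichment. Returns term, k, K, n, N, p, fold_enrichment, significant,
    rank.
    """
    uni = set(universe)
    query = set(gene_list)
    if not query:
        return pd.DataFrame(columns=["term", "k", "K", "n", "N", "p",
                                     "fold_enrichment", "significant", "rank"])
    if not query <= uni:
        raise ValueError("gene list must be contained in the universe")
    n, N = len(query), len(uni)

    rows = []
    for term, members in gene_sets.items():
        term_in_uni = set(members) & uni
        K = len(term_in_uni)
        k = len(term_in_uni & query)
        if K == 0:
            rows.append((term, 0, 0, n, N, 1.0, math.nan))
            continue
        res = fisher_enrichment(
            EnrichmentInputs(universe_size=N, term_size=K, list_size=n, overlap=k),
            ease=ease,
        )
        rows.append((term, k, K, n, N, res.test.p_value, res.fold_enrichment))
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p",
                                        "fold_enrichment"])
    table["significant"] = table["p"] < alpha
    table = table.sort_values(["p", "fold_enrichment"],
                              ascending=[True, False], kind="stable")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def top_terms(enrichment: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k most significantly enriched terms (reporting helper)."""
    return enrichment.nsmallest(k, "rank")


def volcano_table(table: pd.DataFrame, top_n: int = 20) -> pd.DataFrame:
    """Per-gene volcano export: signed log2 fold, -log10 p_FDR, class,
    and a flag marking the ``top_n`` most significant genes for labeling."""
    if table.empty:
        raise ValueError("DE table is empty")
    fold = table["fold_regulation"].to_numpy()
    log2_fold = np.sign(fold) * np.log2(np.abs(fold))
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(table["p_fdr"].to_numpy())
    out = pd.DataFrame(
        {
            "log2_fold_regulation": log2_fold,
            "neg_log10_p_fdr": neg_log10,
            "class": table["direction"].to_numpy(),
        },
        index=table.index,
    )
    order = table.sort_values(["p_fdr", "p"], kind="stable").index
    out["top_label"] = False
    out.loc[order[:top_n], "top_label"] = True
    return out
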