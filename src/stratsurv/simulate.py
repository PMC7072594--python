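"""Synthetic multi-study cohort generator.

Produces log2 expression matrices with one index gene whose level drives a
proportional-hazards effect through a latent cutpoint, planted up/down
differentially expressed genes, exponential survival with independent
exponential censoring, and an ordinal grade associated with the index
gene. All randomness flows through a single seeded generator so outputs
are bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .survival import SurvivalRecord

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_study",
    "generate_gene_sets",
    "generate_ihc_table",
    "write_gmt",
]

_INDEX_MEAN = 10.0
_INDEX_EXTRA_SPREAD = 1.0  # between-sample spread added to noise_sd


class ConfigurationError(ValueError):
    """Raised when a simulation parameter is out of range; names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 200
    n_genes: int = 1000
    index_gene_name: str = "INDEX"
    true_cutpoint_quantile: float = 0.6
    hazard_ratio_hi_vs_lo: float = 2.0
    baseline_event_rate: float = 0.1
    censoring_rate: float = 0.05
    n_de_genes_up: int = 0
    n_de_genes_down: int = 0
    de_log2_effect: float = 1.0
    noise_sd: float = 1.0
    grade_levels: tuple[str, ...] = ("GS<=6", "GS=7", "GS>=8")
    grade_shift: float = 0.5
    seed: int = 0
    horizon: float = 100.0  # administrative censoring cap, time units
    planting_seed: int | None = None  # shared across studies -> same DE gene ids

    def __post_init__(self) -> None:
        checks = [
            ("n_samples", self.n_samples >= 2),
            ("n_genes", self.n_genes >= 1),
            ("true_cutpoint_quantile", 0.0 < self.true_cutpoint_quantile < 1.0),
            ("hazard_ratio_hi_vs_lo", self.hazard_ratio_hi_vs_lo > 0),
            ("baseline_event_rate", self.baseline_event_rate > 0),
            ("censoring_rate", self.censoring_rate > 0),
            ("n_de_genes_up", self.n_de_genes_up >= 0),
            ("n_de_genes_down", self.n_de_genes_down >= 0),
            ("de_log2_effect", self.de_log2_effect >= 0),
            ("noise_sd", self.noise_sd > 0),
            ("grade_levels", len(self.grade_levels) >= 1),
            ("horizon", self.horizon > 0),
            ("n_de_genes_up + n_de_genes_down",
             self.n_de_genes_up + self.n_de_genes_down < self.n_genes),
        ]
        for name, ok in checks:
            if not ok:
                raise ConfigurationError(f"invalid configuration field: {name}")


@dataclass(frozen=True)
class SyntheticStudy:
    expression: pd.DataFrame  # genes x samples, log2
    clinical: pd.DataFrame  # sample_id, time, event, grade
    truth: dict = field(repr=False, default_factory=dict)

    def survival_records(self) -> list[SurvivalRecord]:
        return [
            SurvivalRecord(sample_id=row.sample_id, time=float(row.time),
                           event=int(row.event))
            for row in self.clinical.itertuples(index=False)
        ]

    def index_expression(self, gene: str) -> pd.Series:
        if gene not in self.expression.index:
            raise KeyError(f"index gene {gene!r} not in expression matrix")
        return self.expression.loc[gene]


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Simulate one cohort under the configured generative model.

    The index gene is Normal(10, noise_sd + 1); samples above its
    ``true_cutpoint_quantile`` empirical quantile form the "hi" group whose
    event hazard is multiplied by ``hazard_ratio_hi_vs_lo``. Survival and
    censoring times are exponential; follow-up is capped at ``horizon``.
    Planted up/down genes shift their mean by +/- ``de_log2_effect`` in hi
    samples; all other genes are identically distributed in both groups.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_samples, cfg.n_genes

    sample_ids = [f"S{i:04d}" for i in range(n)]
    gene_ids = [f"G{i:05d}" for i in range(g)]
    gene_ids[0] = cfg.index_gene_name

    # index gene and latent hi/lo assignment
    idx_expr = rng.normal(_INDEX_MEAN, cfg.noise_sd + _INDEX_EXTRA_SPREAD, size=n)
    cut = float(np.quantile(idx_expr, cfg.true_cutpoint_quantile))
    hi = idx_expr > cut

    # ordinal grade from index-gene tertiles plus label noise
    n_levels = len(cfg.grade_levels)
    qs = np.quantile(idx_expr, np.linspace(0, 1, n_levels + 1)[1:-1]) if n_levels > 1 else []
    grade_idx = np.searchsorted(qs, idx_expr, side="right")
    jitter = rng.integers(-1, 2, size=n) * (rng.random(n) < 0.2)
    grade_idx = np.clip(grade_idx + jitter, 0, n_levels - 1)
    # grade feeds back into the index gene: higher grade, higher expression
    if cfg.grade_shift != 0.0 and n_levels > 1:
        idx_expr = idx_expr + cfg.grade_shift * (grade_idx - grade_idx.mean())
        cut = float(np.quantile(idx_expr, cfg.true_cutpoint_quantile))
        hi = idx_expr > cut
    grades = np.asarray(cfg.grade_levels)[grade_idx]

    # survival: exponential with group-specific hazard, exponential censoring
    hazard = np.where(hi, cfg.baseline_event_rate * cfg.hazard_ratio_hi_vs_lo,
                      cfg.baseline_event_rate)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / cfg.censoring_rate, size=n)
    t_cens = np.minimum(t_cens, cfg.horizon)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)  # time must stay strictly positive

    # background genes and planted effects
    base_means = rng.uniform(5.0, 12.0, size=g)
    expr = rng.normal(base_means[:, None], cfg.noise_sd, size=(g, n))
    expr[0, :] = idx_expr

    plant_rng = (rng if cfg.planting_seed is None
                 else np.random.default_rng(cfg.planting_seed))
    de_pool = plant_rng.permutation(np.arange(1, g))
    up_idx = de_pool[: cfg.n_de_genes_up]
    down_idx = de_pool[cfg.n_de_genes_up: cfg.n_de_genes_up + cfg.n_de_genes_down]
    expr[np.ix_(up_idx, np.where(hi)[0])] += cfg.de_log2_effect
    expr[np.ix_(down_idx, np.where(hi)[0])] -= cfg.de_log2_effect

    expression = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)
    expression.index.name = "gene_id"
    clinical = pd.DataFrame({
        "sample_id": sample_ids,
        "time": time,
        "event": event,
        "grade": grades,
    })
    truth = {
        "cutpoint": cut,
        "cutpoint_quantile": cfg.true_cutpoint_quantile,
        "hazard_ratio": cfg.hazard_ratio_hi_vs_lo,
        "up_genes": [gene_ids[i] for i in up_idx],
        "down_genes": [gene_ids[i] for i in down_idx],
        "hi_samples": [s for s, h in zip(sample_ids, hi) if h],
        "config": asdict(cfg),
    }
    return SyntheticStudy(expression=expression, clinical=clinical, truth=truth)


def generate_gene_sets(
    genes: list[str],
    n_sets: int,
    set_size_range: tuple[int, int],
    enriched_set_overlap: float = 0.0,
    seed: int = 0,
    enriched_from: list[str] | None = None,
) -> dict[str, list[str]]:
    """Random gene sets in GMT layout (name -> members).

    When ``enriched_from`` is given and ``enriched_set_overlap > 0``, the
    first set ("SET_ENRICHED") draws that fraction of its members from the
    supplied genes (planted DE genes, typically) so downstream enrichment
    recovery is testable.
    """
    lo, hi = set_size_range
    if not (1 <= lo <= hi):
        raise ValueError("set_size_range must satisfy 1 <= lo <= hi")
    if hi > len(genes):
        raise ValueError("set sizes exceed the number of available genes")
    if not (0.0 <= enriched_set_overlap <= 1.0):
        raise ValueError("enriched_set_overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes_arr = np.asarray(genes)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if i == 0 and enriched_from and enriched_set_overlap > 0.0:
            pool = [g for g in enriched_from if g in set(genes)]
            n_enr = min(int(round(enriched_set_overlap * size)), len(pool))
            chosen = list(rng.choice(pool, size=n_enr, replace=False))
            rest_pool = genes_arr[~np.isin(genes_arr, chosen)]
            chosen += list(rng.choice(rest_pool, size=size - n_enr, replace=False))
            sets["SET_ENRICHED"] = sorted(chosen)
        else:
            members = rng.choice(genes_arr, size=size, replace=False)
            sets[f"SET_{i:04d}"] = sorted(members.tolist())
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path,
              description: str = "synthetic") -> None:
    lines = [
        "\t".join([name, description] + list(members))
        for name, members in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def generate_ihc_table(
    n_patients: int,
    cores_per_class: int,
    benign_mean_score: float,
    malignant_mean_score: float,
    seed: int = 0,
    score_sd: float = 40.0,
) -> pd.DataFrame:
    """Per-core immunohistochemistry table with H-scores whose class means
    match the requested values in expectation.

    Each row carries patient id, tissue class, percent positive cells in
    [0, 100] and an integer intensity in {0, 1, 2, 3}; the H-score is
    percent * intensity. Target scores are drawn Normal(mean, score_sd)
    and decomposed into the smallest admissible intensity.
    """
    for name, mean in (("benign_mean_score", benign_mean_score),
                       ("malignant_mean_score", malignant_mean_score)):
        if not 0.0 <= mean <= 300.0:
            raise ValueError(f"{name} must lie in [0, 300], got {mean}")
    if n_patients < 1 or cores_per_class < 1:
        raise ValueError("n_patients and cores_per_class must be positive")

    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        pid = f"P{p:03d}"
        for cls, mean in (("benign", benign_mean_score),
                          ("malignant", malignant_mean_score)):
            for _ in range(cores_per_class):
                target = float(np.clip(rng.normal(mean, score_sd), 0.0, 300.0))
                if target == 0.0:
                    intensity, percent = 0, 0.0
                else:
                    intensity = min(3, max(1, math.ceil(target / 100.0)))
                    percent = target / intensity
                rows.append((pid, cls, percent, intensity,
                             percent * intensity))
    return pd.DataFrame(rows, columns=["patient_id", "class", "percent_positive",
                                       "intensity", "h_score"])


def write_study(study: SyntheticStudy, outdir: str | Path,
                prefix: str = "study") -> dict[str, Path]:
    """Write expression/clinical TSVs and the truth record as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / f"{prefix}_expression.tsv",
        "clinical": outdir / f"{prefix}_clinical.tsv",
        "truth": outdir / f"{prefix}_truth.json",
    }
    study.expression.to_csv(paths["expression"], sep="\t", float_format="%.10g")
    study.clinical.to_csv(paths["clinical"], sep="\t", index=False,
                          float_format="%.10g")
    paths["truth"].write_text(json.dumps(study.truth, indent=2, sort_keys=True))
    return paths
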