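"""End-to-end orchestration: per-study cutpoint search, survival testing,
differential expression, cross-study intersection and enrichment, driven
by a flat key/value (YAML) configuration and fully deterministic given the
configuration and seed."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cutpoint import find_optimal_cutpoint, selection_adjusted_p
from .diffexp import (DEFAULT_ALPHA, DEFAULT_FOLD_THRESHOLD,
                      cross_study_intersection, de_per_study, enrich_gene_list,
                      volcano_table)
from .io import clinical_to_records, read_clinical, read_expression_matrix, read_gmt
from .survival import cox_univariate, km_estimate, logrank_test, risk_table

logger = logging.getLogger("stratsurv")

__all__ = ["StudyInput", "PipelineConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class StudyInput:
    name: str
    expression_path: Path
    clinical_path: Path


@dataclass(frozen=True)
class PipelineConfig:
    studies: tuple[StudyInput, ...]
    index_gene_name: str
    output_dir: Path
    gene_sets_path: Path | None = None
    min_group_fraction: float = 0.1
    alpha: float = DEFAULT_ALPHA
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD
    min_studies: int = 2
    seed: int = 0
    ease: bool = True
    n_permutations: int = 0  # 0 disables the selection-adjusted p
    equal_variance: bool = False
    collapse_duplicates: bool = False

    def __post_init__(self) -> None:
        if len(self.studies) < 1:
            raise ValueError("at least one study is required")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.fold_threshold <= 1.0:
            raise ValueError("fold_threshold must exceed 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat key/value YAML configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    studies = tuple(
        StudyInput(name=s["name"],
                   expression_path=base / s["expression"],
                   clinical_path=base / s["clinical"])
        for s in raw["studies"]
    )
    kwargs = {k: raw[k] for k in (
        "index_gene_name", "min_group_fraction", "alpha", "fold_threshold",
        "min_studies", "seed", "ease", "n_permutations", "equal_variance",
        "collapse_duplicates") if k in raw}
    gmt = raw.get("gene_sets")
    return PipelineConfig(
        studies=studies,
        output_dir=base / raw.get("output_dir", "results"),
        gene_sets_path=(base / gmt) if gmt else None,
        **kwargs,
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all result tables under
    ``config.output_dir``. Returns the in-memory result bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    de_tables: dict[str, pd.DataFrame] = {}
    study_summaries: dict[str, dict] = {}
    universe: set[str] = set()

    for study in config.studies:
        logger.info("processing study %s", study.name)
        expr = read_expression_matrix(study.expression_path,
                                      collapse_duplicates=config.collapse_duplicates)
        clinical = read_clinical(study.clinical_path)
        if config.index_gene_name not in expr.index:
            raise ValueError(
                f"index gene {config.index_gene_name!r} absent from study {study.name}"
            )
        missing = [s for s in clinical["sample_id"] if s not in expr.columns]
        if missing:
            raise ValueError(
                f"study {study.name}: clinical samples missing from expression: "
                f"{missing[:10]}"
            )
        n_in = expr.shape[1]
        # samples without survival data are excluded everywhere (logged)
        used = [c for c in expr.columns if c in set(clinical["sample_id"])]
        excluded = sorted(set(expr.columns) - set(used))
        if excluded:
            logger.info("study %s: excluding %d samples without clinical data: %s",
                        study.name, len(excluded), excluded[:10])
        expr = expr[used]
        clinical = clinical.set_index("sample_id").loc[used].reset_index()
        records = clinical_to_records(clinical)

        index_expr = expr.loc[config.index_gene_name]
        cut = find_optimal_cutpoint(index_expr, records,
                                    min_group_fraction=config.min_group_fraction)
        adj_p = None
        if config.n_permutations > 0:
            adj_p = selection_adjusted_p(
                cut, records, index_expr,
                n_permutations=config.n_permutations, seed=config.seed,
                min_group_fraction=config.min_group_fraction,
            )

        lo = [r for r in records if cut.labels[r.sample_id] == "lo"]
        hi = [r for r in records if cut.labels[r.sample_id] == "hi"]
        mh = logrank_test(lo, hi, "mantel-haenszel")
        gw = logrank_test(lo, hi, "gehan-wilcoxon")
        cox = cox_univariate(index_expr.loc[[r.sample_id for r in records]].to_numpy(),
                             records)

        km_frames = []
        risk_frames = []
        grid = np.linspace(0, max(r.time for r in records), 6)
        for label, recs in (("lo", lo), ("hi", hi)):
            curve = km_estimate(recs)
            km_frames.append(pd.DataFrame({
                "group": label,
                "time": curve.event_times,
                "survival": curve.survival,
                "at_risk": curve.at_risk,
                "events": curve.events,
            }))
            risk_frames.append(pd.DataFrame({
                "group": label,
                "time": grid,
                "at_risk": risk_table(curve, grid),
            }))

        _write_tsv(cut.candidate_table, out / f"{study.name}_cutpoint_candidates.tsv",
                   index=False)
        _write_tsv(pd.concat(km_frames), out / f"{study.name}_km.tsv", index=False)
        _write_tsv(pd.concat(risk_frames), out / f"{study.name}_risk_table.tsv",
                   index=False)

        de = de_per_study(expr, cut.labels, alpha=config.alpha,
                          fold_threshold=config.fold_threshold,
                          equal_variance=config.equal_variance,
                          exclude_genes=(config.index_gene_name,))
        de_tables[study.name] = de
        universe |= set(expr.index) - {config.index_gene_name}
        _write_tsv(de, out / f"{study.name}_de.tsv", index=True)
        _write_tsv(volcano_table(de), out / f"{study.name}_volcano.tsv", index=True)

        study_summaries[study.name] = {
            "n_input_samples": n_in,
            "n_used": len(used),
            "n_excluded": len(excluded),
            "excluded_samples": excluded,
            "optimal_threshold": cut.optimal_threshold,
            "n_lo": cut.n_lo,
            "n_hi": cut.n_hi,
            "mantel_haenszel": {"statistic": mh.statistic, "p": mh.p_value},
            "gehan_wilcoxon": {"statistic": gw.statistic, "p": gw.p_value},
            "selection_adjusted_p": adj_p,
            "cox": {
                "beta": cox.beta, "hr": cox.hr, "se": cox.se,
                "ci_low": cox.ci_low, "ci_high": cox.ci_high,
                "p": cox.p_value, "converged": cox.converged,
                "separation": cox.separation,
            },
            "n_significant_up": int(((de["direction"] == "up")).sum()),
            "n_significant_down": int(((de["direction"] == "down")).sum()),
        }

    intersection = None
    enrichment = {}
    if len(de_tables) >= 2:
        intersection = cross_study_intersection(de_tables,
                                                min_studies=config.min_studies)
        pd.DataFrame({"gene_id": intersection.shared_up}).to_csv(
            out / "shared_up.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": intersection.shared_down}).to_csv(
            out / "shared_down.tsv", sep="\t", index=False)
        if config.gene_sets_path is not None:
            gene_sets = read_gmt(config.gene_sets_path)
            uni = sorted(universe)
            for direction, genes in (("up", intersection.shared_up),
                                     ("down", intersection.shared_down)):
                genes_in_uni = [g for g in genes if g in universe]
                if genes_in_uni:
                    enr = enrich_gene_list(genes_in_uni, gene_sets, uni,
                                           alpha=config.alpha, ease=config.ease)
                else:
                    enr = enrich_gene_list([], gene_sets, uni)
                enrichment[direction] = enr
                _write_tsv(enr, out / f"enrichment_{direction}.tsv", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "index_gene_name": config.index_gene_name,
            "min_group_fraction": config.min_group_fraction,
            "alpha": config.alpha,
            "fold_threshold": config.fold_threshold,
            "min_studies": config.min_studies,
            "ease": config.ease,
            "n_permutations": config.n_permutations,
            "equal_variance": config.equal_variance,
        },
        "studies": study_summaries,
        "intersection": None if intersection is None else {
            "shared_up": intersection.shared_up,
            "shared_down": intersection.shared_down,
            "conflicts": intersection.conflicts,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return {
        "studies": study_summaries,
        "de_tables": de_tables,
        "intersection": intersection,
        "enrichment": enrichment,
        "manifest": manifest,
    }
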