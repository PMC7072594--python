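# stratsurv

Survival-stratified gene-expression analysis toolkit: stratify cohorts by
an index gene's expression using a maximally selected log-rank cutpoint,
test survival differences (Kaplan–Meier, Mantel–Haenszel, Gehan–Wilcoxon,
univariate Cox), run stratified differential expression with
Benjamini–Hochberg FDR and fold-regulation rules, intersect regulated
genes across studies, and test gene-set over-representation with the
classical Fisher or conservative EASE statistic. A seeded synthetic
multi-study generator makes the whole pipeline testable without external
cohort data, and an IHC H-score helper covers tissue-core scoring.

## Package layout

| module | contents |
| --- | --- |
| `stratsurv.stats` | t tests (Welch/pooled), Mann–Whitney U (exact + normal), one-/two-way ANOVA, BH adjustment, Fisher/EASE enrichment, H-score |
| `stratsurv.survival` | Kaplan–Meier, risk tables, weighted log-rank tests, Cox PH (Newton, Breslow ties) |
| `stratsurv.cutpoint` | candidate thresholds, maximally selected cutpoint search, permutation-adjusted p |
| `stratsurv.diffexp` | per-study DE tables, cross-study intersection, enrichment, volcano export |
| `stratsurv.simulate` | synthetic studies, gene-set fixtures, IHC core tables |
| `stratsurv.io` / `stratsurv.pipeline` / `stratsurv.cli` | TSV/GMT readers, end-to-end orchestration, CLI |

## CLI

```bash
stratsurv simulate --n-samples 200 --n-genes 1000 --seed 7 --out data/
stratsurv cutpoint --expression expr.tsv --clinical clin.tsv \
    --gene CAND1 --min-group-frac 0.1 --permutations 1000 --seed 7 --out cut/
stratsurv de --expression expr.tsv --clinical clin.tsv --gene CAND1 --out de.tsv
stratsurv enrich --genes genes.txt --gmt sets.gmt --universe universe.txt --out enr.tsv
stratsurv run --config config.yaml
```

`stratsurv run` reads a flat YAML config:

```yaml
index_gene_name: CAND1
output_dir: results
gene_sets: sets.gmt        # optional
alpha: 0.05
fold_threshold: 1.25
min_studies: 2
n_permutations: 0          # >0 adds a permutation-adjusted cutpoint p
seed: 7
studies:
  - {name: A, expression: a_expr.tsv, clinical: a_clin.tsv}
  - {name: B, expression: b_expr.tsv, clinical: b_clin.tsv}
```

Outputs per study: cutpoint candidate table, KM curves + risk tables, DE
and volcano tables; across studies: shared up/down gene lists, enrichment
tables, and a `manifest.json` recording config, seed and version. Reruns
with the same config and seed are byte-identical.

## File formats

* **Expression**: TSV, first column `gene_id`, remaining columns sample ids, log2 values.
* **Clinical**: TSV with `sample_id`, `time` (> 0), `event` (0/1), optional `grade`.
* **Gene sets**: standard GMT (name, description, tab-separated members).
* **IHC**: TSV with `patient_id`, `class`, `percent_positive` (0–100), `intensity` (0–3).

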