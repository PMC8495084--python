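# dta-meta

Diagnostic test accuracy (DTA) meta-analysis of study-level 2×2 tables, with
everything needed to compare two index tests evaluated on the same patients:

- **Per-study measures** — sensitivity, specificity, likelihood ratios and the
  diagnostic odds ratio (DOR) with exact (Clopper–Pearson) and log-Wald
  confidence intervals; explicit continuity-correction policy for zero cells.
- **Pooling** — fixed-effect and DerSimonian–Laird random-effects
  inverse-variance pooling (proportions on the raw scale, ratio measures on
  the log scale), Cochran-Q / I² / τ² heterogeneity, leave-one-out
  sensitivity analysis.
- **Summary ROC** — the constant linear (Moses–Littenberg) model
  `D = a + b·S`, the implied SROC curve, AUC and the Q\* index with
  delta-method standard errors, and a two-sample Z comparison of two tests.
- **Diagnostics** — Spearman threshold-effect check (logit TPR vs logit FPR)
  and the funnel-plot asymmetry regression of ln DOR on 1/√ESS
  (ESS = 4·n₁·n₂/(n₁+n₂)) for small-study/publication bias.
- **Synthetic data** — a seeded generator of single- and paired-arm panels
  with logit-normal between-study heterogeneity, an adjustable threshold
  effect and an optional small-study bias, so every stage is testable with
  known truth.

## CLI

```sh
# full one- or two-arm analysis -> JSON report (+ optional forest-plot TSVs)
dta-meta run --input studies.csv --config config.yaml --out report.json --tables-dir tables/

# synthetic panels in the same CSV schema
dta-meta simulate --seed 7 --k 8 --out panel.csv
dta-meta simulate --seed 7 --k 8 --paired --out paired.csv

# leave-one-out pooled-estimate table (TSV to stdout)
dta-meta loo --input studies.csv
```

Input CSV columns: `study_id, year (optional), test_label, tp, fp, fn, tn,
design (optional)`. Exit code 0 on success, 2 on validation errors. The
report JSON validates against `src/dta_meta/data/report.schema.json`; the
YAML config accepts the fields of `dta_meta.AnalysisConfig` (model,
correction mode/value, CI level, weighted SROC fit, AUC range, Spearman
scale).

## Python API

```python
import dta_meta as dm

records = dm.read_studies("studies.csv")
ice = [r for r in records if r.test_label == "ICE"]

pooled = dm.pool_measure(ice, "dor", model="random")      # PooledResult
points = [dm.compute_ds(dm.apply_continuity_correction(r), r.study_id) for r in ice]
fit = dm.fit_moses(points)                                # SROCFit (a, b, SEs)
auc, se_auc = dm.sroc_auc(fit)
qstar, se_q = dm.q_star(fit)
dm.compare_tests(qstar, se_q, 0.9127, 0.0616)             # Z test vs another fit
```

## Defaults chosen for reproduction

- Continuity correction: add 0.5 to all four cells of zero-cell studies only.
- Proportions pool on the raw scale (point estimates from raw counts,
  variances from corrected counts), ratio measures on the log scale.
- SROC fit is unweighted least squares; AUC integrates the full (0,1) FPR
  range with a 1e-4 trapezoid grid.
- Random-effects model everywhere by default; all of the above overridable.
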