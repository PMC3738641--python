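# synoclass

Absolute vs relative inflammatory-cell-density methods for synovial tissue
classification.

## The problem

Synovial biopsies are classified immunohistologically by counting cells that
stain for five markers — CD15 (neutrophils), CD68 (macrophages), CD3
(T cells), CD20 (B cells), CD38 (plasma cells) — in the subintima. The
traditional measure is the **absolute density** of each cell type
(cells/mm²). An alternative is the **relative density**: each cell type as a
percentage of the total inflammatory cell population

TIC = CD15 + CD68 + CD3 + CD20 + CD38 (cells/mm²),
rel_m = 100 · abs_m / TIC.

`synoclass` implements the full statistical machinery for comparing the two
representations across six diagnosis groups ordered by inflammation
severity — N (normal) < Orth.A (orthopedic arthropathy) < OA
(osteoarthritis) < EA (early arthritis) < RA (rheumatoid arthritis) < SeA
(septic arthritis):

* **robust group summaries** — the mean of trimmed means at trim factors
  {10, 20, 30}% for groups with n < 12 and {0, 10, 20}% for n ≥ 12, suited
  to these heavy-tailed, zero-inflated data;
* **ratio-of-ratios** contrasts,
  (abs₁/abs₂) / (rel₁/rel₂), per marker and ordered group pair;
* **two-step nonparametric testing** — Kruskal–Wallis gate, then pairwise
  two-sided Mann–Whitney U with Benjamini–Hochberg FDR within each
  75-test family;
* **binary ROC** — Mann–Whitney AUC with the "corrected AUC" convention
  (AUC < 0.5 ↦ 1 − AUC with a reversal flag), DeLong confidence intervals
  with a seeded bootstrap fallback, FDR-adjusted significance, median-AUC
  summaries, and the absolute-vs-relative difference analysis with the
  0.17 outlier threshold and [−0.07, 0.17] agreement band;
* **multicategory ROC** — the hypervolume under the ROC manifold (HUM),
  HUM = P(X₁ < X₂ < … < X₆) for one draw per class in severity order,
  exhaustive or Monte Carlo, with tie-credited tuples so a constant marker
  scores exactly the chance level 1/M! (= 1/720 ≈ 0.0014 for six classes),
  plus marker+TIC combinations via posterior-expected-severity scores;
* **naive-Bayes leave-one-out classification** with confusion matrices and
  deterministic best-first **wrapper feature selection**;
* a **synthetic cohort generator** (zero-inflated log-normal per group ×
  marker) so every stage is testable without access to clinical data, and
  fixtures of the published corrected-AUC grid and confusion matrices for
  the numbers that are derivable from print.

## Worked example

```python
import synoclass as sc

cohort = sc.generate_cohort(sc.default_config(), seed=1)   # 93 samples
profiles = sc.profile_cohort(cohort)                       # adds TIC + rel_*

roc_abs = sc.run_binary_roc(profiles, "absolute", seed=1)
roc_rel = sc.run_binary_roc(profiles, "relative", seed=1)
print("median corrected AUC, absolute:", round(sc.median_corrected_auc(roc_abs), 3))
print("median corrected AUC, relative:", round(sc.median_corrected_auc(roc_rel), 3))

ranking = sc.rank_features(sc.run_hum(profiles, "singles", seed=1))
print(ranking[["rank", "feature", "hum"]].head(4).to_string(index=False))

X, y, names = sc.build_feature_matrix(profiles, "absolute")
sel = sc.wrapper_select(X, y, names)
```

prints

```
median corrected AUC, absolute: 0.86
median corrected AUC, relative: 0.713
 rank feature      hum
    1     TIC 0.254506
    2    CD38 0.099634
    3    CD15 0.083704
    4    CD20 0.071400
```

The absolute representation separates the group pairs better overall
(median corrected AUC 0.86 vs 0.71 over the 75 marker × pair comparisons),
and total inflammation (TIC) discriminates among all six classes better
than any single marker (HUM 0.25 against a chance level of 0.0014) — the
qualitative pattern expected of cohorts in which overall infiltration
rises steeply with severity. On the same cohort the wrapper selects
CD15/CD20/CD38 for the absolute feature set at 62% LOOCV accuracy.

The same pipeline runs from the shell:

```
synoclass simulate --seed 1 --out cohort.csv
synoclass transform cohort.csv --out profiles.csv
synoclass roc profiles.csv --method both --seed 1 --out roc.csv --diff-out diffs.csv
synoclass hum profiles.csv --features singles --seed 1 --out hum.csv
synoclass classify profiles.csv --features absolute --wrapper --out cm.json
synoclass run-all --seed 1 --out-dir results/
```

User data enters as a cohort CSV with columns
`sample_id,group,cd15,cd68,cd3,cd20,cd38` (column names remappable via the
`schema` argument of `read_cohort`).

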