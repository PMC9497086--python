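# immunoscore

Consensus Immunoscore scoring and survival analysis for colon-cancer
cohorts, with a synthetic-cohort generator for fully reproducible testing.

## The problem

The density of tumor-infiltrating T lymphocytes is a strong prognostic
marker in stage I–III colon cancer, often outperforming anatomical staging.
The consensus Immunoscore standardises this signal: CD3+ and CD8+ T-cell
densities (cells/mm²) are measured by digital pathology in two regions — the
tumor core (CT) and the invasive margin (IM) — giving four measurements per
patient. Each density is converted into a percentile of a reference
distribution, and the mean of the four percentiles

```
IS = ( P(CD3, CT) + P(CD3, IM) + P(CD8, CT) + P(CD8, IM) ) / 4
```

is binned into consensus categories with fixed cut-points:

| scheme | bins |
|---|---|
| two   | Lo `[0, 25]` · Int+Hi `(25, 100]` |
| three | Lo `[0, 25]` · Int `(25, 70]` · Hi `(70, 100]` |
| five  | I0 `[0, 10]` · I1 `(10, 25]` · I2 `(25, 70]` · I3 `(70, 95]` · I4 `(95, 100]` |

The lower bin is closed at each printed cut-point (a mean percentile of
exactly 25 is Lo; exactly 70 is Int). Percentiles use the mid-rank
convention, counting reference ties with weight ½.

Downstream, the package implements the survival machinery such validation
studies run: Kaplan–Meier landmark rates with Greenwood/log(−log)
confidence intervals, k-sample log-rank and one-degree trend tests,
center-stratified Cox proportional-hazards models (Efron or Breslow ties)
with Wald summaries and likelihood-ratio model comparison, Harrell's
C-index, restricted-mean-survival-time (RMST) contrasts, and chi-square
relative-importance decompositions. Endpoints are time to recurrence (TTR;
death without recurrence censors), overall survival (OS) and disease-free
survival (DFS), all in months from surgery.

Because patient-level data of such studies are typically not public, the
`synthetic` module generates cohorts with the matching statistical
structure — four care centers, ≈16/59/25 % stage I/II/III, right-skewed
correlated marker densities, a recurrence hazard that decreases with the
true Immunoscore category, ~15 % events over ~6 years, administrative
censoring — and always writes the generating truth next to the data so
parameter-recovery tests are self-describing.

## Worked example

```python
from immunoscore import (SimulationConfig, generate_cohort, score_cohort,
                         endpoints_table, AnalysisConfig, bivariable_table,
                         multivariable_model)

cohort = generate_cohort(SimulationConfig(seed=5))        # n = 423
scores, qc = score_cohort(cohort.markers, cohort.reference)
print(scores["is3"].value_counts().to_dict())

eps = endpoints_table(cohort.patients)
config = AnalysisConfig(endpoint="TTR")
table = bivariable_table(cohort.patients, scores, eps, config)
row = table[(table.variable == "immunoscore_2cat") & (table.level == "Lo")].iloc[0]
print(f"Lo: n={row.n}, 5-yr recurrence-free rate "
      f"{row.rate_60:.1f}% ({row.rate_60_ci_lo:.1f}-{row.rate_60_ci_hi:.1f}), "
      f"HR {row.hr:.2f} ({row.hr_ci_lo:.2f}-{row.hr_ci_hi:.2f}), p={row.hr_p:.3f}")

mv = multivariable_model(cohort.patients, scores, eps, config)
w = mv["wald"]["is_lo"]
print(f"adjusted HR(Lo vs Int+Hi) = {w['hr']:.2f} "
      f"({w['ci_95'][0]:.2f}-{w['ci_95'][1]:.2f}), p={w['p_value']:.3f}; "
      f"LRT p={mv['lrt'].p_value:.4f}")
```

prints

```
{'Int': 199, 'Lo': 154, 'Hi': 70}
Lo: n=154, 5-yr recurrence-free rate 84.6% (77.7-89.5), HR 1.37 (0.81-2.30), p=0.241
adjusted HR(Lo vs Int+Hi) = 1.60 (0.76-3.34), p=0.213; LRT p=0.2195
```

Reading: of the 423 simulated patients, 154 score Low. Their Kaplan–Meier
recurrence-free rate at 60 months is 84.6 %, and the unadjusted
center-stratified Cox hazard ratio of Low versus Int+Hi is 1.37 — at n = 423
with ~60 events a generating ratio of 1.9 is estimated with wide error,
which is exactly what the recovery tests quantify at larger n. The
multivariable model adjusts for age, gender, T- and N-stage, sidedness and
MSI on complete cases, and the likelihood-ratio test compares the clinical
model with and without the Immunoscore term.

The same pipeline is available from the shell:

```
immunoscore simulate --out sim --seed 5
immunoscore score --markers sim/markers.csv --reference sim/reference.csv --out out
immunoscore analyze --cohort sim/cohort.csv --markers sim/markers.csv \
    --reference sim/reference.csv --endpoint TTR --out out --seed 5
```

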