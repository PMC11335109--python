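# dyadlink

Modelling the link between maternal physical and mental health and infant
outcomes, for biostatisticians and epidemiologists working with mother–infant
(dyad) cohort tables.

One row per dyad: maternal demographics and obstetric history (age, marital
status, education, gestation weeks, delivery mode) and three psychological
screening scores — CBTS (childbirth-related post-traumatic stress, 0–30),
EPDS (Edinburgh Postnatal Depression Scale) and HADS (Hospital Anxiety and
Depression Scale) — alongside the infant's behavioral class
(quiet/moderate/contradictory), gender, age, nightly sleep time, wake count
and sleep-onset mode.

The package implements the full analysis pipeline:

1. **Screening** — tie-correct Spearman rank correlations
   ρ = 1 − 6Σdᵢ²/(n(n²−1)) across all 14 indicators, exported as a matrix
   and a |ρ|-sorted pair table.
2. **Feature selection** — impurity importances of a seeded random forest
   (magnitudes, summing to 1) displayed with the sign of each feature's
   Spearman correlation with the target; top-k selection (default k = 4).
3. **Behavior model** — a one-hidden-layer logistic MLP and a random forest,
   each also producing the numeric expectation Σ_c c·p_c, combined by the
   relative-MAE-gap rule on the validation split:

   Δ = (MAE₁ − MAE₂)/max(MAE₁, MAE₂);  if Δ ≤ 0.05:
   Q₁ = MAE₁/(MAE₁+MAE₂), Q₂ = MAE₂/(MAE₁+MAE₂),
   Y = Q₁·Y_MLP + Q₂·Y_RF;  otherwise the higher-error model is discarded.

   A comparison harness fits MLP, RF, RF-MLP, RF-SVM and SVM-MLP with
   per-split accuracy and macro one-vs-rest AUC.
4. **Sleep-quality clustering** — hand-written fuzzy c-means minimising
   J(U,V) = ΣᵢΣₖ uᵢₖᵐ ‖xₖ − vᵢ‖² over min-max-normalised sleep indicators,
   cluster count chosen by the mean silhouette of the hardened labels, and
   an ordinal good/moderate/poor labelling of the three clusters.
5. **Sleep prediction** — seeded random forests predicting the FCM label,
   binned sleep time, wake count and sleep-onset mode from maternal
   indicators, plus scoring of unlabeled dyads.
6. **Synthetic cohorts** — a generator whose moment-matched truncated
   normals, latent-propensity behavior classes and latent sleep-quality
   mixture emulate the study dataset's descriptive statistics and weak rank
   correlations, so every stage is exercisable without the original data.

## Worked example

```python
from dyadlink import (
    GeneratorConfig, generate_dataset, inject_outliers, remove_outliers,
    spearman_rho, fit_ensemble, SplitSpec,
)

cohort = generate_dataset(GeneratorConfig(n_dyads=410, seed=2024))
dirty, _ = inject_outliers(cohort, k=31, seed=2025)
clean, removed = remove_outliers(dirty)
print(len(clean), len(removed))
# 379 31

rho = spearman_rho(clean["epds"], clean["behavior_class"])
print(round(rho, 4))
# 0.173

fit, report = fit_ensemble(
    clean, ["maternal_age", "education", "epds", "hads"], SplitSpec(seed=1)
)
print(fit.rule.mode, round(fit.rule.delta, 3))
# model2_only 0.142
print(round(report.metrics["RF-MLP"]["test"]["accuracy"], 3))
# 0.372
```

The cleaned cohort keeps 379 of 410 rows (the 31 injected out-of-range
records are removed); the EPDS–behavior rank correlation is weakly positive
(here 0.17) as configured; here the validation MAE gap Δ = 0.142 exceeds the
0.05 gate, so the rule discards the MLP and the "combined" predictor is the
forest alone. With the default weak effect sizes the test accuracy sits near
the majority-class rate — detecting so small a signal at n ≈ 380 is not
expected, and the planted-signal tests use stronger effects.

The same run, end to end, from the shell:

```bash
dyadlink run-all --out report/
cat report/model_comparison.csv
```

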