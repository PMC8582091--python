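# fallrisk

A toolkit for building and evaluating a **continuous fall risk score
(cFRs)** in cohorts of community-dwelling older adults (65+), aimed at
epidemiologists and clinical researchers who screen for recurrent fallers.

Fall risk is multifactorial: intrinsic factors (disease burden, physical
impairments, cognition, physical function, balance, fear of falling,
affordance perception, gait) interact with *exposure* (habitual physical
activity and environmental hazards, which create the opportunity for a
fall). Instead of dichotomising each instrument at a cutoff, the cFRs
combines all ten components on a continuous scale:

1. regress each component x_k on age and sex (OLS) over the cohort;
2. take the standardized residual z_k = (x_k − x̂_k) / SD(residuals);
3. flip the sign of the six protective components (cognition, physical
   function, balance, affordance accuracy, gait, physical activity);
4. sum: **cFRs = Σ_k s_k · z_k**, s_k ∈ {+1, −1}.

The score has mean 0 over the fitting sample; higher values mean higher
risk. Participants with ≥ 2 self-reported falls in the last 12 months are
*recurrent* fallers; the score's ability to identify them is evaluated by
ROC analysis (AUC with Hanley–McNeil CI, Youden-optimal cutoff,
sensitivity/specificity with Wilson CIs, bootstrap PPV/NPV).

The package also ships:

* a **synthetic cohort generator** whose defaults reproduce the published
  two-group structure of a 504-person study sample (29.4% recurrent
  fallers), so every stage is testable without access to raw data;
* **fully conditional specification (FCS) multiple imputation** (m = 8
  completions by chained stochastic regressions) for the missing cells
  typical of such cohorts;
* group-comparison statistics (t, χ², Cohen's d with 90% CI and magnitude
  bands, one-way ANOVA + Tukey HSD) and the finite-population sample-size
  formula.

See `docs/methods.md` for the model details and `docs/column_dictionary.md`
for the CSV schema.

## Worked example

Run the whole pipeline (simulate → impute → score → evaluate → report) on
a default synthetic cohort:

```sh
fallrisk pipeline --out demo_run --seed 1
```

`demo_run/roc_report.json` then contains (abridged):

```json
{
 "auc": 0.8955879124899393,
 "auc_ci": [0.861307585893231, 0.9298682390866476],
 "band": "moderately_accurate",
 "youden_cutoff": 1.7537768295426361,
 "confusion": {
  "tp": 117, "fp": 33, "tn": 313, "fn": 41,
  "sensitivity": 0.740506329113924,
  "specificity": 0.9046242774566474,
  "ppv": 0.78,
  "npv": 0.884180790960452
 }
}
```

Reading: on this synthetic cohort of 504, the cFRs separates recurrent
from occasional fallers with AUC 0.896 (moderately accurate band,
0.7 < AUC ≤ 0.9). Classifying "recurrent" at cFRs ≥ 1.75 (the cutoff
maximising Youden's J) catches 74.1% of recurrent fallers while correctly
clearing 90.5% of occasional fallers; 78% of those flagged are truly
recurrent. `demo_run/table_one.csv` holds the group-characteristics table
(for example, the cFRs contrast on this run: −1.56 vs 3.42, Cohen's
d = 1.80, p < 1e-59), and `demo_run/anova_tukey.csv` the three-group
(0 / 1 / 2+ falls) ANOVA.

The same stages are available individually (`fallrisk simulate`,
`impute`, `score`, `evaluate`, `report`) and as library calls:

```python
from fallrisk import table1_defaults, generate_cohort, impute_fcs, \
    score_cohort, roc_curve

cfg = table1_defaults(); cfg.n = 504; cfg.seed = 1
cohort = generate_cohort(cfg)
pooled = impute_fcs(cohort, m=8, seed=1).pooled()
scores = score_cohort(pooled)
roc = roc_curve(scores.cfrs, pooled.recurrent_indicator())
print(round(roc.auc, 3), roc.band)        # 0.896 moderately_accurate
```

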