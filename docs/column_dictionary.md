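# Cohort CSV column dictionary

One row per participant; header required; missing values are empty cells
or `NA`. Numeric cells are written with at most 6 significant digits.

| column | type | range | description |
|---|---|---|---|
| `id` | string | unique | anonymised participant code (generated if absent) |
| `age` | number | ≥ 65 | age in years |
| `sex` | string | `F`/`M`/`female`/`male` (case-insensitive) | stored canonically as `female`/`male` |
| `falls_12m` | integer | ≥ 0 | self-reported falls in the previous 12 months |
| `chronic_diseases` | integer | ≥ 0 | number of chronic comorbidities |
| `physical_impairments` | integer | 0–6 | reported impairments (dizziness, incontinence, vision, feet, hearing, balance loss) |
| `cognitive` | integer | 0–30 | Mini-Mental State Examination total (higher = better) |
| `physical_function` | integer | 0–24 | Composite Physical Function scale total (higher = better) |
| `balance` | integer | 0–40 | Fullerton Advanced Balance scale total (higher = better) |
| `fear_of_falling` | integer | 16–64 | Falls Efficacy Scale–International total (higher = more fear) |
| `affordance_error` | number | ≥ 0 | absolute error of the stepping-forward estimate, cm |
| `gait` | integer | 0–12 | Tinetti gait section total (higher = better) |
| `physical_activity` | number | ≥ 0 | IPAQ MET-min/week |
| `environmental_hazards` | integer | 0–34 | dwelling hazards counted |
| `weight_kg`, `height_cm`, `waist_cm`, `bmi` | number | optional | body composition; `bmi` must equal `weight_kg / (height_cm/100)²` when all present |

Scored CSVs additionally carry `z_<component>` (unsigned age/sex-adjusted
standardized residuals) and `cfrs` (the signed sum).
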