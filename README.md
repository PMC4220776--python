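# utilmap

Map FACT-G cancer-specific quality-of-life scores onto EQ-5D and SF-6D
health-utility indices.

Economic evaluations of cancer treatments need utilities — preference
weights anchored at 1 (full health) and 0 (dead) — to compute
quality-adjusted life years, but trials usually administer only a
cancer-specific instrument such as the FACT-G (27 items, four well-being
domains, global score 0–108).  `utilmap` implements the standard remedy:
*mapping* (crosswalking) regressions that predict a preference-based index
from FACT-G responses,

u = f(x'β) + ε,

estimated three ways on each of three nested predictor sets:

| estimator | prediction rule | why |
|---|---|---|
| OLS (HC1-robust SE)        | x'β          | the conventional baseline |
| GLM, log link              | exp(x'β)     | multiplicative mean for a bounded response |
| CLAD (bootstrap SE)        | min(x'β, 1)  | median regression consistent under the ceiling effect (~23% of EQ-5D responses sit exactly at 1) |

Predictor sets: **1** rescaled FACT-G global score; **2** rescaled
PWB/FWB/EWB domain scores; **3** model 2 plus age, sex, tumour-site and
stage dummies.  The package also ships the published coefficient table as
ready-made crosswalks, a full validation battery (MAE, RMSE, adjusted R²,
Spearman, exact Wilcoxon signed-rank, percentile and severity-subgroup
summaries), FACT-G scoring with FACIT proration rules, a generic additive
tariff engine for preference instruments, and a synthetic cohort generator
calibrated to the published marginal statistics so the whole pipeline is
testable without patient data.  See `docs/methods.md` for the model and
calibration details.

## Worked example

```python
import pandas as pd
from utilmap import CohortConfig, generate_cohort, run_mapping_study, CladConfig

cohort = generate_cohort(CohortConfig(n=367, seed=42))   # synthetic study cohort
res = run_mapping_study(cohort, seed=7, clad_config=CladConfig(bootstrap_reps=200))
print(res.comparison.query("spec == 1")[
    ["target", "method", "spec", "Constant", "FACT-G",
     "adj_r2", "rmse_dev", "rmse_val", "mae_val", "n"]
].round(3).to_string(index=False))
```

```
target method  spec  Constant  FACT-G  adj_r2  rmse_dev  rmse_val  mae_val   n
  eq5d    OLS     1     0.270   0.008   0.381     0.116     0.131    0.102 181
  eq5d    GLM     1    -0.889   0.009     NaN     0.116     0.134    0.103 181
  eq5d   CLAD     1     0.242   0.008     NaN     0.117     0.130    0.098 181
  sf6d    OLS     1     0.197   0.007   0.456     0.093     0.084    0.068 184
  sf6d    GLM     1    -1.088   0.010     NaN     0.092     0.084    0.068 184
  sf6d   CLAD     1     0.194   0.007     NaN     0.093     0.084    0.068 184
```

The 367 synthetic patients are split 184/183 into development and
validation halves; each row is one estimator fitted on the development half
of Model 1 (constant + rescaled FACT-G global score, so a slope of 0.008
means 0.008 utility per rescaled FACT-G point).  `rmse_dev`/`rmse_val` and
`mae_val` are in-sample and held-out prediction errors on the utility
scale; `n` is the development rows remaining after listwise deletion
(a few patients have a missing utility, mirroring the study's Ns).
Adjusted R² and log-likelihood are reported where the estimator defines
them.

Applying the *published* coefficients to new patients instead (the
recommended crosswalk per target is CLAD for EQ-5D, GLM for SF-6D):

```python
from utilmap.crosswalk import load_published_coefficients, crosswalk_predict
coeffs = load_published_coefficients("EQ5D", "CLAD", 1)
crosswalk_predict(pd.DataFrame({"factg": [60, 80, 100]}), coeffs,
                  convention="rescaled")
```

```
 utility  missing_predictor
   0.658              False
   0.750              False
   0.843              False
```

i.e. a patient with a raw FACT-G global score of 80 (74.1 rescaled) maps to
an EQ-5D utility of 0.75.  The `convention` argument is mandatory because
the scale on which the published coefficients were estimated is ambiguous;
see `docs/methods.md`.

The same operations are available from the shell:

```bash
utilmap simulate --n 367 --seed 42 --out cohort.csv
utilmap study --cohort cohort.csv --seed 7 --out table.csv
utilmap crosswalk --in cohort.csv --target eq5d --model 1 --out utilities.csv
```

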