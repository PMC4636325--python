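# penregsim

Monte-Carlo comparison of penalized regression and stepwise variable
selection for low-dimensional clinical models with correlated predictors.

## The problem

In metabolic studies, insulin sensitivity (measured by a clamp or a
frequently sampled IV glucose tolerance test) is routinely modelled by
linear regression on a panel of correlated predictors: repeated
oral-glucose-tolerance-test (OGTT) measurements of glucose, insulin,
C-peptide, proinsulin and amylin, plus anthropometry. Samples are small
(often n ≈ 50–110) and the predictors are strongly collinear, so ordinary
least squares and automatic stepwise selection produce unstable
coefficients — frequently with the *wrong sign*, a serious interpretation
hazard when positively correlated predictors compete in one model.

`penregsim` is a simulation laboratory for this setting. It compares, under
controlled generative conditions,

* **OLS** — the naive fit;
* **sAIC / sBIC** — stepwise-backward selection minimizing
  `AIC = n·ln(RSS/n) + 2k` or `BIC = n·ln(RSS/n) + k·ln(n)`;
* **Ridge, LASSO and three elastic-net tuning strategies** for the
  penalized objective

  ```
  Σᵢ (yᵢ − β₀ − xᵢᵀβ)²  +  λ₁ Σⱼ|βⱼ|  +  λ₂ Σⱼ βⱼ²        (β₀ unpenalized)
  ```

  with λ's chosen by 10-fold cross-validation: **Enet 1** tunes λ₁ first
  (λ₂ = 0) then λ₂; **Enet 2** the opposite order; **Enet 3** searches
  (λ₁, λ₂) jointly.

Methods are scored on prediction RMSE (fresh evaluation data), coefficient
bias and RMSE, selection probability, wrong-sign frequency and model
complexity.

## Synthetic scenarios

No external data is needed. Predictors are multivariate normal with unit
variance and a correlation matrix *calibrated so each variable's variance
inflation factor* `VIF_j = 1/(1 − R²_j)` (the j-th diagonal of the inverse
correlation matrix) hits a target:

* **Scenario A** — k = 20 grouped assay summaries with heterogeneous true
  effects, VIFs from 1.0 (an orthogonal noise variable `h`) to 33.3,
  σ = 0.4; a high-collinearity *prediction* setting.
* **Scenario B** — k = 9 serially correlated glucose-curve time points,
  all true effects −0.025, VIF targets 2.76–7.61, σ = 0.3; a
  *coefficient-accuracy* setting.
* **Scenario C** — as B with four coefficients (i.2, i.3, i.8, i.9) set to
  zero and σ = 0.15; a *selection-under-correlated-noise* setting.

The response is `y = 1.45 + Xβ + ε`, `ε ~ N(0, σ²)` throughout.

## Worked example

```python
from penregsim import StudyConfig, run_study

cfg = StudyConfig(scenarios=("B",), sample_sizes=(50,), replicates=200,
                  methods=("OLS", "sBIC", "Ridge", "LASSO"), master_seed=7)
summary = run_study(cfg)[("B", 50)]
print(summary.per_method[["rmse_y", "complexity", "lambda1_median", "lambda2_median"]].round(4))
print(summary.wrong_sign_table())
```

prints

```
       rmse_y  complexity  lambda1_median  lambda2_median
OLS    0.3360       9.000             NaN             NaN
sBIC   0.3267       1.725             NaN             NaN
Ridge  0.3133       9.000          0.0000         58.8891
LASSO  0.3182       4.030          2.4232          0.0000

                 OLS        sBIC       Ridge       LASSO
variable
i.1       34.0 (0.0)  2.0 (80.5)  11.0 (0.0)  3.0 (48.5)
i.2       42.5 (0.0)  1.0 (85.5)  13.5 (0.0)  2.5 (59.5)
...
```

Reading: at n = 50 every shrinkage method beats OLS on out-of-sample RMSE
(0.313–0.318 vs 0.336; the irreducible error is σ = 0.3). OLS keeps all
nine variables and estimates the wrong sign for a variable in ~34–44% of
replicates; the lasso selects four variables on average and nearly
eliminates wrong signs (2.5–5.5%), at the price of excluding each variable
about half the time. Stepwise BIC is sparsest (1.7 variables) but excludes
true effects in ~80% of replicates. The parenthesized number is the
exclusion percentage; ridge and OLS never exclude.

The same comparison is available from the shell:

```bash
penregsim simulate --config configs/scenario_b_desk.yaml --out out/
penregsim fit --method lasso --lambda1 2 --data mydata.csv
penregsim calibrate --targets vifs.csv --structure banded-serial
penregsim report --records out/records_B_n50.csv --scenario B --n 50
```

## Layout

| module | contents |
| --- | --- |
| `penregsim.correlation` | VIF computation; VIF-targeted synthesis of correlation matrices (serial-Markov and grouped-factor families) |
| `penregsim.scenarios` | `ScenarioSpec`, built-in scenarios A/B/C, dataset generation |
| `penregsim.estimators` | `PenalizedRegression` (coordinate descent / closed-form ridge), OLS, regularization paths |
| `penregsim.selection` | information criteria, `StepwiseRegression` |
| `penregsim.tuning` | K-fold CV error, 1-D and joint penalty searches, `CVTunedRegression` |
| `penregsim.evaluation` | replicate records, per-method and per-variable metric summaries |
| `penregsim.experiment` | `StudyConfig`, `run_study`, deterministic seed derivation |
| `penregsim.cli` | `penregsim` command-line entry point |

All estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn model-selection tooling. See `docs/methods.md` for the statistical
conventions and design choices.
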