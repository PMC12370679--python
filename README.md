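# pinecrown

Models of secondary-branch size distribution in planted Korean pine
(*Pinus koraiensis*) crowns, for forest biometricians and crown-
structure modelers. Secondary branches — the second-order shoots
carrying most of a conifer's foliage — grow longer and thicker from
the primary-branch tip inward and then taper toward the branch base.
`pinecrown` provides the full quantitative toolchain for that pattern:

* **Candidate growth curves** — nine classical forms (Richards,
  Weibull, Logistic, Hossfeld, Schumacher, Mitscherlich, Roeecp, Korf,
  Gompertz) of the tip-to-base distance `SDINC`, with analytic
  gradients. The unimodal Roeecp curve `f(x) = a·x^b·e^(−c·x)` (peak
  at `x = b/c`) is the workhorse.
* **Fixed-effects fitting and selection** — bounded nonlinear least
  squares, AIC/RMSE/adjusted-R² screening across candidates, and an
  exhaustive search for linear covariate expansions of the curve
  parameters (`a ← a + a1·PDINC` for branch length,
  `b ← b + b1·PBD` for branch diameter).
* **Two-level nonlinear mixed-effects estimation, written from
  scratch** — random perturbations of curve parameters at the
  primary-branch level (`b_i, c_i ~ N(0, D1)`) and the whorl-within-
  branch level (`b_ij ~ N(0, D2)`), residuals `N(0, σ²)`, estimated by
  maximum likelihood with a Lindstrom–Bates alternating algorithm, a
  Laplace likelihood evaluator, and an adaptive Gauss–Hermite
  refinement of the fixed effects. Optional heteroscedastic variance
  functions and AR(1)/MA(1)/ARMA(1,1) within-whorl correlation.
* **Allometric scaling** — log–log OLS scaling exponents between
  primary- and secondary-branch sizes at three grouping levels, with
  percentile-bootstrap confidence intervals (3,000 replicates, 95%).
* **Crown-profile summaries** — whorl-wise and age-group mean
  profiles, current-year shoot extraction, and the relative depth at
  which the size profile peaks.
* **A calibrated synthetic-crown generator** — hierarchical datasets
  (54 trees, ~720 primary branches, ~24,000 secondary branches at the
  defaults) with covariates drawn inside published summary envelopes
  and responses drawn from the fitted mixed-model laws, so the entire
  pipeline is testable without any field data.

Estimators follow scikit-learn conventions (`fit`, `predict`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn tooling; thin module-level functions mirror each step.

## Worked example

```python
from pinecrown.synth import GeneratorConfig, generate_dataset
from pinecrown.growth import ModelSpec
from pinecrown import nls
from pinecrown.nlme import TwoLevelNLME

ds = generate_dataset(GeneratorConfig(seed=42, n_trees=12,
                                      response_law="SBL_mixed"))
df = ds.to_frame()          # 164 primary branches, 5,338 secondaries

# 1. which curve fits branch length best?
screen = nls.screen_candidates(df, response="SBL")
print(screen[["function_id", "name", "aic", "rmse"]].head(3))
#  function_id     name          aic      rmse
#           M7   Roeecp 49015.825977 23.843902
#           M9 Gompertz 49024.628439 23.863569
#           M3 Logistic 49030.100061 23.875803

# 2. two-level mixed model with the depth covariate on the amplitude
est = TwoLevelNLME(spec=ModelSpec("M7", {"a": "PDINC"}),
                   level1=("b", "c"), level2=("b",)).fit(df)
print(est.beta_)
# {'a': 0.254, 'a1': 0.0004, 'b': 0.9232, 'c': 0.0024}
print(est.result_.variance_report())
# {'sigma2': 256.0, 'var_b_level1': 0.00743, 'var_c_level1': 4.03e-06,
#  'corr_bc_level1': 0.843, 'var_b_level2': 0.00193}
```

The screen puts the Roeecp curve first by AIC, matching its role as
the selected base model. The mixed fit recovers the generating law of
this simulated crown (amplitude ≈ 0.2 plus 3×10⁻⁴ per cm of crown
depth, exponent ≈ 1, residual variance ≈ 252 cm²) within the sampling
error of a 12-tree subsample; mixed-model RMSE drops to 15.0 cm from
23.8 cm for the population-average curve, the gain coming from the
branch- and whorl-level effects. `est.predict(new_rows,
mode="subject")` adds each group's empirical best predictor;
`mode="population"` uses the fixed effects alone.

A command-line interface covers the same steps
(`pinecrown generate | screen | nlme | allometry | profile | run`);
`pinecrown run --seed 7 --out-dir out/` executes the whole pipeline
and writes delimited tables plus a reproducibility manifest.

## Layout

| module | contents |
| --- | --- |
| `pinecrown.growth` | candidate curves, gradients, peak locations |
| `pinecrown.nls` | `GrowthCurveRegressor`, screening, covariate search |
| `pinecrown.nlme` | `TwoLevelNLME`, Laplace likelihood, LRT, random-effects search |
| `pinecrown.allometry` | `PowerLawAllometry`, bootstrap CIs, scaling profiles |
| `pinecrown.summaries` | whorl/age-group means, current-year shoots, peak depth |
| `pinecrown.synth` | generator, envelopes, CSV round-trip |
| `pinecrown.pipeline`, `pinecrown.cli` | orchestration and CLI |

See `docs/methods.md` for the statistical details and design choices.
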