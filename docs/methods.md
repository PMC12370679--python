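# Methods

`pinecrown` models the size of second-order (secondary) branches in
planted Korean pine (*Pinus koraiensis*) crowns: how branch length
(SBL, cm) and basal diameter (SBD, mm) vary with the position of the
branch along its parent first-order (primary) branch, and how branch
sizes scale allometrically across the crown. This note documents the
models, the synthetic-data generator, the estimation algorithms and the
numerical choices.

## The mean model

Nine classical growth curves are available as candidate mean functions
of `SDINC`, the distance (cm) from the primary-branch tip to the
secondary-branch base: Richards, Weibull, Logistic, Hossfeld,
Schumacher, Mitscherlich, Roeecp, Korf and Gompertz (ids `M1`–`M9`).
All are increasing-saturating on their admissible parameter boxes
except the Roeecp curve

    f(x) = a * x^b * exp(-c*x),

which rises and then falls, peaking at `x = b/c` — the shape branch
size actually follows inside a crown, and the curve selected by AIC on
both responses. Any base parameter can be expanded linearly in one
covariate; the two extensions used by the headline pipeline are

    SBL: (a + a1*PDINC) * SDINC^b * exp(-c*SDINC)
    SBD: a * SDINC^(b + b1*PBD) * exp(-c*SDINC)

with `PDINC` the distance (cm) from the tree tip to the primary-branch
base and `PBD` the primary-branch diameter (mm). Analytic gradients are
implemented for every curve and verified against high-order finite
differences.

## The two-level mixed model

Secondary branches are nested in whorls (annual cohorts, index j)
within primary branches (index i). The mixed model perturbs chosen
curve parameters at both levels:

    y_ijk = f(beta + B b_i + M b_ij, v_ijk) + e_ijk
    b_i ~ N(0, D1),  b_ij ~ N(0, D2),  e_ijk ~ N(0, sigma2 * Lambda_ij)

For branch length the selected structure is branch-level effects on
`(b, c)` and a whorl-level effect on `b`; for diameter, branch-level
`(b, c)` and a whorl-level effect on the slope `b1`. `D1` and `D2` are
unstructured; no tree-level effect is included, keeping the two-level
nesting of the field design. `Lambda` is the identity by default; a
power or exponential variance function and AR(1)/MA(1)/ARMA(1,1)
within-whorl correlation are implemented and tested on synthetic
heteroscedastic data, but the headline pipeline runs with
`G = Gamma = I` because the selected models carry no residual
structure.

### Estimation

Maximum likelihood (never REML, so AIC and likelihood-ratio tests are
comparable across fixed-effect structures) by a Lindstrom–Bates-style
alternating algorithm:

1. **Conditional modes.** Given variance parameters, the random-effect
   modes are updated by penalized Gauss–Newton: the model is linearized
   in the effects and the update is the ridge (BLUP) solution of the
   working linear mixed model.
2. **Variance parameters.** At the linearization around the modes, the
   working-model profiled likelihood (fixed effects and `sigma2`
   profiled out in closed form) is maximized over the log-Cholesky
   factors of `D1/sigma2` and `D2/sigma2` plus any variance-function or
   correlation parameters, by Nelder–Mead with warm starts across outer
   iterations. The log-Cholesky parameterization keeps both matrices
   positive semidefinite by construction; they are reported as
   variances plus correlations.

The loop stops when the relative log-likelihood change falls below
1e-8 (default) or after 200 outer iterations, and reports which
criterion triggered. All linear algebra is blockwise and loop-free:
whorl blocks are handled by a rank-q2 Woodbury identity (or batched
dense blocks when within-whorl correlation is active) and the
branch level by a q1 x q1 capacitance per group, with contiguous
segment sums over the sorted observation table.

### Quadrature refinement of the fixed effects

Linearization-based ML is known to bias fixed effects when random
effects enter the curve strongly nonlinearly. Here the branch-level
effects perturb an exponent over a wide within-branch range of
`log(SDINC)`, and at the default generating values the pure
linearization estimator overshoots the amplitude `a` by roughly 20% —
a behavior we reproduced independently with `nlme::nlme` in R on
identical data, while an importance-sampling evaluation of the exact
marginal likelihood showed that exact ML prefers the generating values.
The fitter therefore finishes with an adaptive Gauss–Hermite stage:
holding the variance parameters at their ML estimates, it re-maximizes
over the fixed effects the marginal likelihood with the branch-level
effects integrated on a 5^q1-node adaptive grid (centered at the
conditional modes, scaled by the conditional information), whorl
effects still integrated by conditional linearization. Optimization
runs in Wald-SE-scaled coordinates (BFGS), and the centering is
refreshed once. This removes the amplitude bias (recovery simulations
below) at a cost of a few seconds per fit; it can be disabled with
`refine=False`.

The reported log-likelihood remains the Laplace-approximate marginal
likelihood at the conditional modes, which coincides with adaptive
quadrature whenever the curve is linear in the random effects (tested
against a dense Gauss–Hermite oracle). `AIC = -2*logLik + 2k` with `k`
counting fixed effects, free covariance entries, `sigma2` and any
variance/correlation parameters.

### Robustness guards

The working GLS step for the fixed effects is accepted only if it does
not increase the conditional residual sum of squares by more than 0.1%;
otherwise it is step-halved (up to six times). Fixed effects are
projected into the curve's admissible box after each update. Variance
ratios through which a single effect would claim more than 50x the
weighted residual variance are rejected inside the variance-parameter
search, and conditional modes beyond eight prior standard deviations
are clipped. A non-finite likelihood triggers one restart from the NLS
initialization ("ridge restart"); a second failure returns a flagged,
non-raised result. When a variance function or correlation structure is
active, the first variance-parameter search is multi-started over that
direction, which escapes a local basin observed with the power variance
function.

### Initial values

Fixed effects start from the population-average NLS fit. For the
Roeecp curve the NLS start is the exact log-linearization
`log y = log a + b log x - c x` solved by OLS on the positive
responses; the saturating curves anchor their asymptote at 1.05 times
the maximum response and linearize the remainder. Relative variance
starts let each effect explain ~5% of the NLS residual variance
through its gradient column.

## Fixed-effects fitting, model screening, covariate search

Population-average fits use bounded trust-region least squares
(`scipy.optimize.least_squares`, analytic Jacobians, 500-evaluation
cap, relative tolerance 1e-10). Non-convergence is data, not an
exception: screening sweeps return flagged rows that rank last, which
mirrors how a screening table reports candidates that fail on a given
response. Reported indices: `RMSE = sqrt(RSS/n)`, MAE, adjusted
`Ra2 = 1 - (1-R2)(n-1)/(n-p-1)`, Gaussian ML log-likelihood, and
`AIC = -2 logLik + 2(p+1)` counting the residual variance as a
parameter. The covariate search enumerates placements in which each of
`a`, `b`, `c` is expanded by at most one candidate covariate, rejects
placements whose added slope is not significant at 0.05 (the retention
threshold is our choice; retained slopes are typically far below it),
and ranks survivors by AIC.

## Allometric scaling

Paired sizes are modeled as `y = a x^b`, fitted as log–log OLS; the
slope is the scaling exponent. Percentile-bootstrap CIs use case
resampling with `B = 3000` replicates and a 95% level by default, fully
vectorized and deterministic given the seed; the interval is the pair
of empirical `(1 +/- level)/2` quantiles of the replicate slopes.
Grouping levels: by primary-branch age and by tree age, pairing each
primary branch with the secondary branch at its base (operationalized
as the deepest whorl, maximum SDINC); and by secondary-branch age,
pairing branch size against the tip-to-attachment distance (length) or
against the parent diameter scaled by relative depth (diameter) — the
latter stands in for mid-branch diameters that are not measured in
felling campaigns, and is flagged as an approximation. Groups with
fewer than 5 pairs are reported but marked unreliable.

## Crown-profile summaries

Whorl-wise and age-group means are exact grouped means with tip-first
ordering; current-year shoots are the `SAGE = 1` subset summarized
against primary-branch age. The "inflection point" is defined as the
relative depth (`SDINC/PBL`) at which the mean size profile peaks —
consistent with a profile that increases and then decreases — not a
second-derivative zero; both a 10-bin binned-argmax estimate and a
fitted-curve estimate (`b/c` capped at the branch length, averaged over
branches) are exposed, with the binned form as default. A monotone
profile returns 1.0 with a flag. Stand age classes are 28, 40, 46, 53,
64 and 70 years.

Note that at the default generating values the length curve peaks at
`b/c ~ 330 cm`, beyond the average branch length (~244 cm), so the
pooled binned profile of fully synthetic data rises essentially
monotonically; an interior peak appears once branch lengths exceed the
curve peak, which is how the profile-shape test constructs its truth.

## The synthetic-data generator

The generator emulates a felled-tree branch census: 54 sample trees
across six even-aged stands (28–70 years), 11–16 primary branches per
tree, one secondary-branch whorl per year of branch age, and 1–Poisson
observations per whorl, giving ~720 primaries and ~24,000 secondaries
at the defaults — the scale of the study design it mirrors. Tree and
branch covariates are truncated normals inside published summary
envelopes (min/mean/max/sd); branch depth (PDINC) increases with
branch age; branch length follows a unimodal depth profile calibrated
so its marginal mean (~240 cm) and spread (~120 cm) match the
envelope; branch diameter is log-linear in branch length plus noise;
whorl positions sit at `j/(n_whorls+1)` of the branch length with ±7%
jitter. Responses follow the mixed-model laws above at the published
parameter estimates (the defaults in `RESPONSE_LAWS`), with the
`(b_i, c_i)` cross term read as a correlation (0.842 length, 0.891
diameter): read as a covariance it would exceed
`sqrt(var_b * var_c)` and make `D1` indefinite.

Residual errors are kept exactly Gaussian, so a few percent of
simulated sizes are nonpositive (physically impossible but
statistically faithful). The alternative of redrawing nonpositive
responses is available (`nonpositive="redraw"`, rejection rate
recorded), but it truncates the error law: at the default length-model
values it rejects ~11% of draws, inflates the mean error by +2.6 cm
and deflates the realized residual variance by ~17%, which would
invalidate every variance-recovery check. Parameter-recovery
simulations therefore use the exact-Gaussian default.

What the generator does not emulate: 3-D crown geometry, light
interception, between-covariate dependence beyond the stated links
(e.g., PDINC and SDINC are conditionally independent given branch
size), foliage biomass, and measurement error in covariates. Passing
recovery tests therefore demonstrate that the estimators recover the
generating laws under the study's hierarchical design — not that the
published field estimates are correct.

## Problem sizes and tolerances in the test suite

Unit tests run at reduced scale (typically 4–18 trees). The
parameter-recovery acceptance tests use 12 trees (~160 primaries,
~5,500 secondaries) and 10 replicates, asserting replicate means
within two Monte-Carlo standard errors for fixed effects and 5% for
the residual variance; the acceptance script runs the same protocol at
the full 54-tree census scale. Oracle tolerances: Laplace vs dense
Gauss–Hermite 1e-4; log–log OLS vs closed form 1e-12; bootstrap bounds
vs a brute-force resampling loop exact at a shared seed; analytic
gradients vs finite differences at relative 1e-5 to 1e-6. Bootstrap
coverage is checked over 500 simulated datasets at `B = 3000`
(binomial tolerance around 95%).

## Known limitations

* The quadrature refinement integrates only the level-1 effects
  exactly; a small residual approximation error from the whorl level
  remains (a few percent on the amplitude at the default length-model
  values, within the recovery tolerances).
* Wald standard errors come from the working GLS information and are
  not refreshed after the quadrature stage.
* Likelihood values from linearization-based software can differ from
  the Laplace values reported here by small systematic offsets; AIC
  comparisons within the package are internally consistent.
* The likelihood-ratio test uses the chi-square reference; when a
  variance component sits on the boundary of its space the test is
  conservative.
* With all variance components near zero the variance-parameter search
  can only approach the boundary (log-Cholesky factors cannot reach
  exactly zero); estimates shrink to numerically negligible values
  instead.
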