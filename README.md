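# splinemlm

Multivariate multilevel **linear-spline growth models** for parallel change
processes — e.g. maternal weight and mean arterial pressure (MAP) across
pregnancy.

Life-course epidemiology often asks not just how a variable changes over
time, but whether change in one variable *precedes* change in another.
`splinemlm` fits joint piecewise-linear growth models for two (or more)
repeatedly measured variables by maximum likelihood, and turns the
individual-level covariance of their random intercepts and period slopes
into interpretable, mutually adjusted regression coefficients with honest
standard errors.

## The model

For individual *k*, response *i* at occasion *j*:

```
y_ijk = β0_i + Σ_l β_il s_il(t_jk) + u_i0k + Σ_l u_ilk s_il(t_jk) + ε_ijk
```

where `s_il(t)` is the *l*-th linear-spline basis component for response
*i* (time spent in period *l* by time *t*, periods delimited by knots), the
random effects `u_k = (u_10k, u_11k, …, u_2m2k) ~ N(0, G)` capture each
individual's deviation from the mean intercept and the mean slope of every
period, and the occasion-level residuals are bivariate across responses
measured at the same occasion, `ε ~ N(0, R)`, homogeneous over time.

The package provides:

- **Constrained ML fitting** (`splinemlm.fit`): profile likelihood over the
  variance parameters with an analytic score; selected entries of `G` can
  be fixed to exactly zero.
- **Temporal hypotheses** (`same_or_adjacent_only`, `precedence`,
  `block_effect_vs_response`, `lag`): each compiles to a set of
  zero-constrained covariances whose cardinality is the df of the
  likelihood-ratio test against the unconstrained model (`splinemlm.lrt`).
- **Adjusted regressions among random effects**
  (`coefficients`, `adjusted_regression`): solve `Σ β = σ₀` on blocks of
  `G`, with three standard-error methods — moment-based (as if `G` were
  sample moments of *n* individuals), delta method using the sampling
  covariance `Γ` of the `G` entries, and simulation (draw `vech(G)` from
  `N(vech(Ĝ), Γ)` and re-solve, percentile CIs).
- **SEM view** (`build_layout`, `implied_moments`, `check_equivalence`):
  the equivalent latent growth-curve parameterisation on a balanced weekly
  grid, with spline-basis factor loadings.
- **Synthetic data** (`generate`, `default_generator`): unbalanced
  bivariate antenatal-style datasets with known truth, for validation and
  power exploration.

## Worked example

```python
import splinemlm as sm

# weight: knots at weeks 18 and 29; MAP: knots at 18, 29 and 36;
# baseline week 8, horizon week 44
specs = (sm.WEIGHT_SPEC, sm.MAP_SPEC)

# How many covariances does each temporal hypothesis fix to zero?
print(len(sm.same_or_adjacent_only(specs)))                  # 8
print(len(sm.precedence(specs, "map", "weight")))            # 3
print(len(sm.precedence(specs, "weight", "map")))            # 5
print(len(sm.block_effect_vs_response(
    specs, sm.slope("map", 1), "weight")))                   # 4

# Likelihood-ratio test from two fitted deviances at 4 df
print(sm.lrt_from_deviances(984211.981, 984228.987, 4))
# chi2 = 17.006, df = 4, p = 0.002

# Adjusted regression on a published 9x9 random-effect covariance:
# MAP at week 8 per kg of weight at week 8
q = sm.AdjustmentQuery(outcome=sm.intercept("map"),
                       predictors=(sm.intercept("weight"),))
effects = sm.ModelSpec(responses=specs).effects
print(sm.coefficients(sm.REFERENCE_G, q, effects))  # [0.21381...] mmHg/kg
```

An end-to-end simulation round trip:

```python
gspec = sm.default_generator(n_individuals=500, seed=1)
data, truth = sm.generate(gspec)          # ~10,000 rows, 2 responses
fitted = sm.fit(gspec.model_spec(), data) # ML fit of the 9-effect model
res = sm.adjusted_regression(
    fitted,
    sm.AdjustmentQuery(outcome=sm.slope("map", 2),
                       predictors=(sm.slope("weight", 1),)),
    seed=1,
)
print(res.table())
```

`res.table()` lists the coefficient (mmHg/week of MAP change in weeks
18–29 per kg/week of weight gain in weeks 8–18) with moment, delta and
simulation standard errors — the moment intervals are systematically
narrowest because they ignore that `G` is itself estimated.

A CLI mirrors the library (`splinemlm simulate/fit/test/lrt/adjust/sem-check`);
run `splinemlm --help`.

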