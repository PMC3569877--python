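# Methods

## Model

`splinemlm` fits a multivariate two-level (occasions within individuals)
linear-spline growth model. Time is reparameterised per response into `m`
piecewise-linear basis components: component `l` at time `t` is the length
of overlap of `[baseline, t]` with period `l`, so components are
nonnegative, sum to `t − baseline` inside the observation window, and the
mean trajectory `intercept + Σ slope_l · basis_l(t)` is continuous with
kinks exactly at the knots. The last period is open-ended: times past the
horizon keep accruing on the final component (with a warning); the horizon
only delimits the period intervals used by the adjacency rules.

Each response contributes a random intercept and one random slope per
period at the individual level; the stacked random-effect vector is
`u_k ~ N(0, G)` with `G` unstructured (or with selected covariances fixed
to zero). Occasion-level residuals are jointly normal across responses
measured at the same occasion with a time-homogeneous covariance `R`
(variance per response, one cross-response covariance for a bivariate
model). Two rows belong to the same occasion iff they share the individual
and the occasion time; data recorded at finer-than-week resolution should
be rounded (`round_to_week`) before fitting so that cross-response matching
is well defined — rounding also reduces between-individual variation in
measurement times, which helps convergence.

Covariates enter the fixed part of each response as intercept shifts only;
covariate-by-spline interactions are out of scope.

## Estimation

Estimation is straight ML (not REML): deviances of models with identical
fixed parts are compared directly, and the SEM equivalence is stated for
full-information ML. For fixed variance parameters the fixed effects are
the GLS solution, so the likelihood is profiled and only the free unique
entries of `G` plus the unique entries of `R` are optimised (L-BFGS-B).
Free entries are optimised directly on the covariance scale — an
unconstrained Cholesky parameterisation cannot represent entry-wise zeros —
scaled by the geometric means of initial variances for conditioning.
Feasibility is enforced implicitly: any parameter value for which some
individual's marginal covariance `Z_k G Z_k' + R_k` fails its Cholesky
factorisation receives a large penalty, and the line search backtracks into
the feasible region. Note the feasible set is marginal positive
definiteness, which is slightly larger than `G ⪰ 0`; a fitted `G` with a
(numerically) negative eigenvalue is possible for weakly identified effects
and is surfaced by the correlation utilities.

The analytic score uses the standard identities: for a `G` entry,
`∂ℓ/∂G_ab` follows from `Σ_k Z_k'W_k Z_k` and the outer products of
`Z_k'W_k r_k` (`W_k = V_k⁻¹`, `r_k` the GLS residual); for `R` entries the
trace/quadratic terms are accumulated over the sparse occasion-matching
pattern. Individuals are grouped by observation count and all per-group
linear algebra is batched.

Starting values: per-response least squares on the spline basis gives the
scale; the residual variance is split into a between-individual part
(initial intercept variance, slope variances scaled by the squared time
span) and a within part (initial `R` diagonal). A cheap variances-only
pre-optimisation (all free covariances pinned at zero) then supplies the
start for the full problem — the staged strategy of adding covariance
structure to an already-converged simpler model. Convergence: relative
deviance change below 1e-9 (configurable `ftol`) or scaled-gradient
threshold; non-convergence returns best-so-far parameters with
`converged=False` and a warning, never a crash.

`Γ`, the sampling covariance of the unique `G` entries (needed by the delta
and simulation SE methods), is the inverse observed information of the
profile likelihood at the optimum, computed by central differences of the
analytic score on the raw covariance scale (step 1e-4 of each parameter's
scale; one-sided fallback at feasibility boundaries; pseudo-inverse with a
warning if the information is not PD). Rows and columns of constrained
entries are zero. A Monte-Carlo calibration (120 replicate fits of a
univariate random-intercept/slope design) shows these SEs track the
empirical sampling SDs within a few percent.

## Hypotheses and likelihood-ratio tests

Temporal hypotheses are sets of covariances fixed to zero; the LRT df is
the set's cardinality. Interval conventions, chosen once and used
everywhere: periods are closed intervals sharing boundary points; two
periods are *adjacent* when the closed intervals intersect (overlap or a
shared knot), and period B is *subsequent* to period A when
`start(B) ≥ end(A)` — the immediately following, boundary-sharing period
counts as subsequent. Under these rules the example structure (weight
periods [8,18],[18,29],[29,44]; MAP periods [8,18],[18,29],[29,36],[36,44])
yields 8 constraints for same-or-adjacent-only association (within- and
cross-response slope pairs; intercepts never constrained), 3 for "MAP
change does not precede weight change", 5 for the reverse direction, and 4
for blocking the early-MAP slope against everything of weight. The
same-or-adjacent generator exposes `include_within`; the default includes
within-response pairs, which the cross-only reading would reduce to 4. The
lag rule measures the hypothesised lag in period indices, which equals a
time gap when both responses share one knot set; for unequal knot sets the
index-gap reading is a documented choice, not a claim.

Negative LRT statistics (restricted fit below the full fit) indicate
non-convergence; they are reported with `p = 1` and a warning rather than
clipped silently.

## Adjusted regressions and standard errors

Regressions among random effects solve `Σ β = σ₀` on blocks of `G`.
Method 1 (moment) uses `SE_j = sqrt(s² d_j / (n − p − 1))` with
`s² = σ₀₀ − σ₀'Σ⁻¹σ₀` and `d = diag(Σ⁻¹)`; it reproduces a textbook
multiple-regression fit exactly when `G` holds ddof-1 sample moments, and
its intervals are anti-conservative because they ignore the sampling
uncertainty of `G`. Method 2 (delta) propagates `Γ` through the analytic
differential `dβ = Σ⁻¹(dσ₀ − dΣ·β)`. Method 3 (simulation) draws
`vech(G)` from `N(vech(Ĝ), Γ)` (eigen-factorised, so a singular `Γ` from
constrained fits is handled), re-solves per draw, and reports the mean and
2.5th/97.5th percentiles; draws with a non-PD predictor block are skipped
and counted rather than projected — projection would bias the percentiles —
and more than 50% skips aborts, since the normal approximation for the
(co)variance estimates is a large-sample device. Default `q = 10,000`
draws; the seed is mandatory. Reporting rescales (per 10 kg, per
0.4 kg/week, …) are applied only in `AdjustedRegression.table()`;
coefficients are stored in natural units.

Population associations must be computed from the model-estimated `G`, not
from the empirical covariance of predicted individual effects: best linear
unbiased predictions are shrunken towards zero in proportion to each
individual's information, so their empirical covariance understates `G`
(asserted as a directional test on synthetic data).

## SEM view

On a balanced grid (integer weeks by default) the model is a latent growth
curve model: intercept factors with unit loadings, slope factors loaded by
the spline basis at each grid time, factor covariance `G`, residual
structure `R` with cross-response covariance only within a grid time.
`check_equivalence` rebuilds both moment sets from one fitted parameter
vector and reports the maximum absolute discrepancy (numerical precision,
~1e-12); no second estimator is included, because re-estimating by FIML
would duplicate the fitting engine rather than test anything new. Grid
cells before a response's baseline are flagged unusable and excluded.

## Synthetic data

The generator emulates antenatal-care records: per-woman visit counts from
a rounded normal (mean 10, SD 3.5) clipped to 1–18, visit times drawn
without replacement from integer weeks 8–43 with a mild linear
late-pregnancy enrichment (3% relative weight per week), both responses
measured at every visit unless a per-response drop probability is set.
The true visit-time process behind the emulated summaries (median ~10,
range 1–18) is not identifiable from summaries alone; the schedule model is
a documented stand-in and fully configurable. Defaults for the truth:
the published 9 x 9 random-effect covariance of the pregnancy cohort
analysis (PD-projected by eigenvalue clipping at 1e-8 if the printed
rounded entries were indefinite — the shipped matrix is in fact already
PD), population curves shaped like the cohort averages (weight ~65 kg at
week 8 rising 0.33/0.50/0.45 kg/week; MAP ~85 mmHg dipping −0.30 then
rising 0.10/0.55/0.60 mmHg/week), and occasion-level covariance
var(weight) = 1.6 kg², var(MAP) = 24 mmHg², cov = 0.3 — measurement-noise
magnitudes plausible for clinic scales and sphygmomanometers. What passing
tests show is therefore internal validity (the estimator recovers the
mechanism it assumes) — not robustness to features real cohorts add:
informative visit timing, missing-not-at-random dropout, digit preference
in blood-pressure readings, or covariate-dependent visit schedules.

Utilities mirror standard preparation steps: MAP = systolic/3 +
2·diastolic/3, and random thinning to at most one measurement per
individual x response x 2-week window (seeded), used to limit the influence
of individuals with many closely spaced measurements.

## Validation problem sizes

The test suite validates at sizes chosen to make Monte-Carlo noise
negligible while keeping a laptop run short: likelihood oracle equivalence
on 100 random tiny instances (tolerance 1e-10); parameter recovery of the
full 9-effect model over 20 replicates of n = 500 women (every `G` entry
within 3 reported SEs of truth in ≥ 18/20 replicates); SE-method
concordance at n = 2500 (delta vs simulation CI widths within 5%);
cross-checks of the univariate fitter against an independent mixed-model
implementation at n = 300.

## Known limitations

- Two levels only (occasions in individuals); no third level of nesting.
- Continuous responses with normal random effects and residuals; no
  categorical outcomes, no growth-mixture extensions.
- Occasion-level covariance is homogeneous over time by design (mirroring
  the equal-residual-variance constraints of the SEM formulation).
- Missingness is assumed ignorable (MAR); no sensitivity analysis for
  non-ignorable mechanisms is provided.
- Knot locations are user-supplied; no automatic knot search.
- With many splines and few observations per individual, `G` is weakly
  identified: the fitter warns, and constrained models can fail to reach
  the unconstrained optimum's neighbourhood (visible as small negative LRT
  statistics).
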