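# Methods

## The model

`sitarbayes` fits a shape-invariant (SITAR-type) growth model to
longitudinal stature. Stature `y_ij` of subject `i` at decimal age `x_ij`
is modelled as

    y_ij = (a0 + a_i) + sum_k beta_k h_k(u_ij) + eps_ij
    u_ij = (x_ij - x_bar - (z0 + z_i)) * exp(-(g0 + g_i))
    eps_ij ~ Normal(0, sigma^2)

where `h_k` are natural cubic spline basis functions on the transformed
age `u`, `x_bar` is the mean age over all records of the fitted cohort,
and each subject deviates from the population curve through three
effects: size `a_i` (cm, vertical shift), timing `z_i` (years, horizontal
shift) and intensity `g_i` (dimensionless log age-scale). The triple
`(a_i, z_i, g_i)` is zero-mean trivariate normal with free SDs and
correlation. Larger `g` stretches a subject's age axis, so velocity
scales by `exp(-g)`: the exponential multiplies the *age argument* of the
spline, the convention under which size, timing and intensity play
distinct roles.

Sexes are always fitted separately; the inclusion filter and `x_bar` are
computed per fitted (sex-specific) cohort.

### Spline basis

Natural cubic splines are built from the truncated-power construction
(the `splines::ns` function space): `K = df` columns, no intercept (the
size parameter `a0` absorbs the constant, removing a likelihood
non-identifiability), boundary knots at the min/max of the transformed
ages and `df - 1` interior knots at equally spaced quantiles. The spline
is exactly linear beyond the boundary knots, so its second derivative
vanishes there identically. Derivatives of all orders are closed-form.
Knots are placed once, at initialisation (`z0 = 0`, `g = 0`), and held
fixed: letting knots move with the sampled transform would make the
posterior ill-defined. `df` defaults to 5 (the 4-6 range customary for
SITAR fits); it is a configuration knob throughout.

We experimented with re-placing knots on the scale of a pilot fit's
transform; the refit simply drifts `g0` to undo the re-scaling and
reproduces the identical curve, so the one-pass placement is kept.

### Priors

Priors are weakly regularising and scaled to the data (SD of stature
`sd_y`, SD of age `sd_x`), all overridable:

| parameter | prior | default scale |
|---|---|---|
| `a0` | Normal(mean stature, 2 sd_y) | data |
| `beta_k` | Normal(0, 5 sd_y) | data |
| `z0` | Normal(0, sd_x) | data |
| `g0` | Normal(0, 1.5) | fixed |
| `sigma` | Half-Student-t(3, sd_y) | data |
| `sd_a` | Half-Normal(sd_y); `sd_z`: Half-Normal(sd_x); `sd_g`: Half-Normal(0.5) | data/fixed |
| correlation | LKJ(2) | fixed |

`prior_sensitivity_sweep` refits with all scale hyperparameters
multiplied by a common factor; on the default synthetic benchmark the
population landmarks move by well under 0.1 years between factors 0.5
and 2.

## Estimation

The joint log density (likelihood + random-effect model + priors) and its
gradient are analytic in every data-touching parameter; the handful of
variance-component transform terms are differentiated numerically (they
cost microseconds per evaluation).

**MAP** (`fit_map`) maximises the joint density over population
parameters, individual effects and variance components together.
Plain quasi-Newton optimisation of the full ~300-dimensional problem is
unreliable here: curvatures span four orders of magnitude and the
variance components create flat directions. The implementation therefore
runs block-coordinate ascent -- (i) curve + effects given variances with
a Gauss-Newton diagonal preconditioner, (ii) variance components given
effects, (iii) residual SD -- iterated to convergence, followed by one
preconditioned joint polish. Initialisation matters: the population
curve comes from a fixed-effects spline regression, initial size effects
from subject-mean residuals, and `sigma` from the *within-subject*
residual spread. (Starting instead from zero effects and the pooled
residual SD makes timing effects a cheaper, wrong proxy for size offsets
and the optimiser can lock into that valley.) MAP is deterministic given
the data.

As with any joint mode of a hierarchical model, MAP variance components
are mildly shrunk relative to posterior means; on the default benchmark
the effect on landmark estimates is small (compare `fit_map` vs
`sample_posterior` in the examples).

**MCMC** (`sample_posterior`) runs static Hamiltonian Monte Carlo on the
unconstrained posterior with a non-centred parameterisation of the
effects (effects = scale matrix x standard-normal deviates). Geometry is
handled in three layers: the population-parameter block is whitened by
the inverse square root of its numeric Hessian at the MAP; the step size
is tuned by dual averaging to a target acceptance (default 0.85); and a
diagonal mass matrix is re-estimated twice during warmup from the chain's
own variances, which also captures the population-vs-effects ridge
directions the MAP Hessian cannot see. Leapfrog counts are drawn
uniformly up to `max_leapfrog` (default 32) to avoid resonances; energy
errors above 1000 count as divergences. Chains start from the MAP plus
jitter. Defaults mirror the study design (2 chains x 6000 iterations,
warmup 3000, all post-warmup draws kept). Split R-hat and bulk ESS
(rank-normalised, via ArviZ) are attached per population parameter, with
warnings -- not exceptions -- above R-hat 1.01 or below ESS 400. On small
cohorts (a few dozen subjects) the variance components mix noticeably
more slowly than the curve parameters; the default 6000-iteration runs
are sized for that.

## Landmarks

The velocity curve of any draw is
`v(x) = exp(-g_tot) * sum_k beta_k h'_k(u(x))`. Because the age
transform is a monotone affine map for fixed parameters, extrema in age
correspond one-to-one to extrema of `g(u) = sum beta_k h'_k(u)` on the
transformed scale. The search runs once per draw on `g`: acceleration
zero-crossings are bracketed on a 2001-point grid and refined by Brent's
method to ~1e-9, far inside the stated 1e-6 tolerance. The peak is the
crossing with the highest velocity; the takeoff is the last minus-to-plus
crossing before the peak, with a flagged window-minimum fallback when the
pre-peak velocity is monotone (spline fits over truncated age ranges can
lose the takeoff dip; the published wide takeoff intervals suggest this
boundary sensitivity is real). Takeoff is *defined* here as the pre-spurt
local minimum of velocity, the standard auxological definition; the
source material never states one.

Individual landmarks use the exact closed forms
`APHV_i = x_bar + z0 + z_i + u* exp(g0 + g_i)` and
`PHV_i = exp(-(g0+g_i)) g(u*)` (and takeoff analogues), verified against
direct per-subject numeric search in the tests.

Point estimates are posterior means of per-draw landmarks -- not the
landmark of the posterior-mean curve, which differs under nonlinearity --
and 68% credible intervals are the 16th-84th percentiles (linear
interpolation between order statistics). Draws whose search fails are
dropped and counted; >10% failures raises an error. Search windows
default to the 5th-95th percentile of observed ages; extrapolated linear
spline tails have no interior extrema and are not searched.

## Maturity classification

Subjects are labelled from posterior-mean individual APHV within sex:
early below the 16th percentile, late above the 84th, average otherwise,
with strict inequalities and linearly interpolated percentile thresholds
(so 200 distinct values split exactly 32/136/32). A mean +/- 1 SD rule is
available behind `rule="sd"`; under normality the two nearly coincide.
Per-draw label uncertainty is exposed as a diagnostic
(`label_uncertainty`). Group summaries average subject point estimates
and pool subject-level draws for the 68% intervals; timing-tempo
correlations are plain Pearson correlations of point estimates, reported
with the stratum size.

## Posterior predictive check

The check mirrors a kernel-density overlay: replicate datasets are
simulated at the observed design points from evenly spaced posterior
draws, and each replicate's stature density is compared with the observed
one through the overlap coefficient `integral min(f_obs, f_rep)` (1 =
identical, 0 = disjoint). The Gaussian-kernel bandwidth is Silverman's
rule on the observed sample, shared with every replicate, so overlap
differences reflect the data rather than bandwidth adaptation. The
density grids are exported for regenerating the overlay plot.

## Sensitivity analyses

`sensitivity_by_min_measurements` refits the model on the subsets of
subjects with at least m measurements (default m in {4,...,11}, covering
both the inclusion rule's 4 and the deeper subsamples) and reports the
landmark estimates per threshold plus their SD across thresholds. Refits
default to MAP for desk-scale runtime; `method="mcmc"` reproduces the
full design. Thresholds leaving fewer than 10 subjects are skipped with a
log entry.

## The synthetic-cohort generator

The study's raw data are not public, so the pipeline is exercised on
synthetic cohorts with known ground truth. The generator's mean velocity
curve is a childhood exponential decay plus a Gaussian pubertal pulse,

    v(t) = c exp(-lambda (t - t0)) + A exp(-(t - mu)^2 / (2 s^2)),

with closed-form height via the error function. This family is
deliberately *not* a SITAR spline: recovery tests force the fitted spline
to approximate a curve outside its own function space. (A spline-mean
generator, `simulate_sitar_cohort`, exists for exact-recovery unit
tests.) The four free parameters `(c, lambda, A, mu)` are calibrated by
root-finding so the curve's takeoff and peak match target landmarks to
1e-3; defaults are the published reference values for Brazilian girls
(ATGV 8.41 yr, TGV 5.85 cm/yr, APHV 11.30 yr, PHV 8.38 cm/yr) and boys
(11.19, 5.43, 13.55, 9.52). Pulse widths are fixed at 1.2 yr (girls) and
1.1 yr (boys); anchor heights 113/115 cm at age 6 are plausible
school-entry statures and do not affect landmarks (size is additive).

Individual curves time-transform the mean curve about the pulse centre:
`t' = mu + (t - mu - z_i) exp(-g_i)`, so `z_i` shifts and `g_i` stretches
the pubertal region exactly as in the fitted model, and true individual
landmarks follow in closed form (`PHV_i = PHV exp(-g_i)`, ages map
affinely). Effects are zero-mean trivariate normal with defaults
`sd_a = 2.5` cm, `sd_z = 0.7` yr, `sd_g = 0.08`, correlations zero except
`corr(z, g) = +0.3` -- the positive timing-intensity coupling that
produces the published *negative* APHV-PHV association (later maturers
have larger `g`, hence slower peaks). Measurement noise is Normal(0,
0.5 cm). None of these magnitudes are estimates of the study population
(they are unreported); they are sized so that group-level contrasts of
the published order (~2.3 years early-vs-late APHV spread) are
attainable.

The measurement schedule is annual visits at ages 6.3, 7.3, ..., 16.3,
recorded with Gaussian age jitter (SD 0.1 yr) and attended independently
with probability 0.985. Two constraints shaped this choice: per-subject
measurement counts must stay within the 4-11 range of the study's
distribution (11 scheduled visits cap the count by construction), and the
inclusion filter must retain >= 90% of subjects (retention ~94-95% under
these defaults). The 0.3-year offset keeps every scheduled visit at
least 3 jitter-SDs inside the inclusion windows (9.9-14.0 girls,
10.9-15.0 boys, entry from age 6), whose edges integer-age visits would
straddle. A 13-visit 6-18 schedule cannot satisfy both constraints at
once: retention high enough for the inclusion rules produces counts of
12-13.

What the generator does *not* emulate: staggered school entry and exit
(every subject shares one schedule, so low counts of 4-6 arise only from
rare missed visits, not attrition), secular trends, non-normal
measurement error, and age-dependent residual variance. Passing recovery
tests therefore show that the pipeline recovers landmarks under the
model's structural assumptions with realistic noise and dropout -- not
that those assumptions hold in any particular school cohort.

## Numerical choices and degenerate inputs

- Duplicate (subject, age) rows are rejected, not averaged; any
  out-of-range or non-numeric row aborts a read (growth modelling is
  sensitive to silent data loss).
- Inclusion windows are closed intervals; endpoints count.
- The correlation matrix is parameterised through tanh-transformed
  canonical partial correlations of its Cholesky factor; `sigma` and the
  SDs through logs. MAP optimises the natural-space density at the
  transformed point (no Jacobian), MCMC includes the change-of-variable
  Jacobians.
- Wide box bounds (far outside physical ranges) keep line-search trial
  points finite; landmark grid searches use 2001 points with Brent
  refinement; ties in the percentile classification fall to `average` by
  the strict-inequality rule.
- Cohorts of a single subject are rejected (random-effect SDs
  unidentifiable); all-equal APHVs refuse classification; constant
  samples refuse a KDE.

## Known limitations

- At `df = 5` the spline population curve slightly under-resolves a
  sharp pubertal peak. On the boys benchmark (pulse width 1.1 yr, peak
  late in the observed age range) the best achievable df=5 approximation
  already sits ~0.2 cm/yr below the true PHV, and the fitted estimate
  lands ~0.6 cm/yr low (MAP and MCMC agree); `df = 6` removes most of
  the bias. Timing landmarks are far more robust than velocity values.
- MAP variance components are joint-mode estimates and mildly shrunk;
  use `sample_posterior` when the variance components themselves are of
  interest.
- The static-HMC sampler is tuned for this model family; it is not a
  general-purpose replacement for NUTS, and very small cohorts mix
  slowly in the variance components.

## Problem sizes in the test suite

The suite exercises the full pipeline at n=100 subjects per sex with MAP
estimation (seconds per fit), MCMC at reduced sizes (10-40 subjects,
hundreds of iterations) for sampler contracts, and a scaled-down
parameter-recovery study (MAP across three seeds at n=60) in place of a
many-replication MCMC design. These sizes are the package's standard
desk-scale benchmark; the full study-scale configuration (2 x 6000
iterations) remains the library default for real analyses.
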