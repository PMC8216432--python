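# Methods

## The trajectory model

Daily responses around a heat-challenge onset (day 0, the switch from
22 °C to 32 °C) are described by a smooth broken-line ("bent-cable"
style) mean function with two threshold days,

    Y(d) = y0 + v1·d − r1·(v1 − v2)·softplus((d − td1)/r1)
                     − r2·v2·softplus((d − td2)/r2),

softplus(x) = ln(1 + e^x).  Far below `td1` the slope is `v1`; between
the thresholds it is `v2`; beyond `td2` it is 0, so the curve ends on a
plateau.  The model is applied to two responses over the window
d ∈ [−1, 10]:

- **feed intake** on the metabolic scale (g/d per kg^0.60 of body
  weight): v1 ≪ 0 with td1 near 0 (the onset collapse), v2 > 0 (gradual
  recovery during acclimation);
- **core body temperature** (°C, daily mean of a continuously logging
  implanted sensor): v1 > 0 (short-term heat storage), v2 < 0 (the
  decline once acclimation sets in), plateau after td2.

The minus sign before the second softplus term is required for the
terminal slope to vanish (v1 − (v1 − v2) − v2 = 0); with a plus sign the
curve would keep drifting at rate 2·v2 and never plateau.

Softplus is evaluated as `logaddexp(0, x)`; a naive `log(1 + exp(x))`
overflows for sharp transitions (small r), which the tests exercise down
to r = 1e−8.

**Sharp limit.**  As r1, r2 → 0 the curve converges to the exact
piecewise-linear broken stick anchored so the first segment passes
through (0, y0).  The pointwise gap is bounded by
r·ln2·(|v1 − v2| + |v2|), attained at the kinks.  The sharp limit is
implemented separately (`evaluate_sharp`) and serves as an independent
oracle for the smooth code path; all *derived trajectory summaries*
(extremum at td1, earliest window minimiser/maximiser, day-10 vs day −1
contrast) are defined on it.  Ties in the earliest-extremum search are
broken toward the earliest day, which makes td2 the earliest minimiser
of a rise-then-fall temperature curve — the natural reading of "the
minimum is reached at the plateau onset", though any day beyond td2
attains the same value.

**Transition widths.**  r1 and r2 are not identifiable with much
precision from daily data and are fixed by default at **0.25 d** for
both responses, shared across groups (transition sharpness is treated as
a property of the response, not of the treatment).  A profiling option
refits over a grid {0.05, 0.1, 0.25, 0.5, 1.0} and keeps the best
log-likelihood, for sensitivity checks.

## Mixed-model estimation

Observations are modelled as

    y_ij = Y(d_ij; θ_g(i)) + b_i + ε_ij,
    b_i ~ N(0, σr²),  ε_ij ~ N(0, σe²),

with a single additive per-animal random intercept: one variance per
fit is reported, and the between-animal spread of whole trajectories is
dominated by level shifts.  Random slopes or multivariate random effects
are out of scope.

Because the random effect is additive and Gaussian, the marginal
likelihood is available in closed form: each animal's marginal
covariance is compound symmetric (σe²·I + σr²·J), giving
log|V_i| = (n_i − 1)·ln σe² + ln(σe² + n_i·σr²) and a quadratic form in
the within-animal residual sums.  The closed form is the production
path.  An **adaptive Gauss–Hermite quadrature** evaluation (nodes
centred at each animal's conditional mode, scaled by the conditional
standard deviation; default 9 nodes) is kept as an independent
cross-check path and agrees with the closed form to ~1e−12 in the
tests; non-adaptive quadrature is also available.

**Optimisation.**  Marginal ML over the per-group mean parameters
(y0, v1, v2, td1, td2; shared r1, r2) and (σr², σe²), by multi-start
L-BFGS-B (default 5 starts, seeded jitter; ties by smaller parameter
norm).  Variance components are optimised on the log scale — they can
sit many orders of magnitude from the mean parameters, and log-scaling
removes the ill-conditioning that otherwise stalls the optimiser in
near-degenerate (noiseless) problems.  Starting values come from a grid
search over (td1, td2) on a 0.25-d lattice, solving the profiled linear
least-squares problem in (y0, v1, v2) on the sharp-limit basis; variance
starts are method-of-moments from the sharp-limit residuals.
Convergence tolerance is 1e−8 on the relative objective change; the
objective history of the winning start is monitored and any increase
marks the fit non-converged.

**Threshold bounds.**  td1 < td2 is kept by a smooth quadratic barrier
below a 0.1-d gap (inactive at interior optima).  Box bounds default to
the **exposure window [0, 10]**: the thresholds are days *of exposure*,
and with daily observations a lower bound below day 0 makes
(y0, v1, td1) practically unidentifiable — a mode with td1 just below
the first observed day and an extreme v1 can reproduce the onset drop
with an arbitrary intercept, because only one observation (day −1)
constrains the first segment.  Estimates pinned at a bound are flagged
(intake fits frequently pin td1 at 0 — the collapse is effectively
instantaneous — exactly as the published estimates of 0.00–0.01 d
suggest).  The wider bound remains available via `FitConfig.td_bounds`.

**Standard errors** come from the inverse observed information
(finite-difference Hessian of the negative marginal log-likelihood via
`statsmodels.tools.numdiff`); if the full matrix is singular (variance
at a boundary) the mean-parameter block is inverted instead.  Estimation
is plain ML, not REML.

**Adjusted R²** uses the reported formula
1 − [SSE/(n − p − 1)]/[CTSS/(n − 1)] with **conditional** residuals —
observed minus (fitted curve + empirical-Bayes intercept
b̂_i = σr²·Σe_ij/(n_i σr² + σe²)) — and p = 5·(number of groups) + 2.
With marginal residuals the between-animal variance would count as
error and the statistic could not reach the ~0.9 values typical of
well-behaved temperature fits.

**Group comparisons** refit all groups jointly (group-specific mean
parameters, shared r and variances) and form pairwise Wald z-tests per
parameter from the joint covariance; letters come from the standard
insert-and-absorb compact letter display at α = 0.05.  Note the
all-parameters-non-significant probability under the null is ~0.95⁵ ≈
0.77 per replicate pair, not 1 − α: the five tests are separate.

## Synthetic cohorts and the study generator

`simulate_trajectories` draws y_ij = Y(d_j) + b_i + ε_ij on integer days
−1…10 from a named preset — the published parameter sets for each
response × period × group, with their variance components (e.g. feed
intake, pooled first challenge: y0 = 179 g/d/kg^0.60, v1 = −39.1,
v2 = 5.34, td1 = 0.01, td2 = 7.97, σr² = 300, σe² = 331; core
temperature: y0 = 39.3 °C, v1 = 0.48, v2 = −0.30, td1 = 1.46,
td2 = 6.30, σr² = 0.038, σe² = 0.036).  Presets must round-trip these
values exactly; rows belonging to a joint fit share its variance
components.  Default cohort sizes follow the source design (18 animals
for the pooled first challenge, 9 per group otherwise).

`simulate_study` rebuilds the whole trial: 5 treatment groups
(TTT, HTT, THT, TTH, HHH — letter = room per period) × 9 pigs × three
15-d periods (relative days −3…11, challenge onset at day 0; weigh days
−3, 0, 5 and the period boundary, so day 12 of one period is day −3 of
the next).  Choices, in the package's own terms:

- **Challenged group-periods** follow their preset trajectory (days
  clipped to the fitted window); HHH uses its period-specific presets in
  P2/P3, which encodes the acclimation attenuation across repeated
  challenges.
- **Thermoneutral feed intake** sits flat at the *prechallenge* level of
  the period's preset, Y_sharp(−1) = y0 − v1, with the same noise
  structure.  Anchoring at y0 instead would put unchallenged intake
  ~20% below the challenged groups' own prechallenge level (y0 is the
  value at onset, already mid-collapse for intake) and create jumps at
  period boundaries; unchallenged groups are reported as
  indistinguishable in intake, so the flat level must match the
  prechallenge plateau.
- **Thermoneutral core temperature** declines linearly with age
  (default −0.01 °C/d from 39.0 °C at the start of the experiment) —
  the slow drift seen in control animals; no within-day rhythm is
  simulated.  The drift rate is a free configuration parameter; no
  published value exists for it.
- **Feed intake is generated on the metabolic scale** and multiplied
  back by BW^0.60 to emit raw g/d, so the pipeline's scaling step is a
  real inverse operation, not a no-op.
- **Body weight** grows linearly (default 1.2 kg/d from ~68.6 kg,
  matching the trial's overall 68 → 120 kg trajectory), modulated by
  relative intake so challenge periods depress gain; weighings add
  N(0, 0.5 kg²) gut-fill/scale noise.  The intake→gain coupling is a
  deliberate simplification (strictly proportional, no maintenance
  partition), so simulated ADG percent drops are milder than intake
  drops, whereas real challenges hit gain hardest.  The severity
  *ordering* across periods is preserved and tested; the ADG magnitudes
  are not calibrated.

What passing tests on these cohorts shows — and does not.  The generator
reproduces exactly the stochastic structure the fitter assumes
(Gaussian intercept + Gaussian residuals around the two-threshold
curve).  Parameter-recovery results therefore validate the estimation
machinery, not the model's adequacy for real trajectories, which can
have heteroscedastic noise, within-day temperature rhythms,
autocorrelated residuals and non-Gaussian animal effects that this
generator deliberately omits.

## Pipeline conventions

- Periods split into half-open intervals [−3, 0), [0, 5), [5, 12) on
  integer days; feed is attributed to the day offered.
- Analysis pools per period: P1 {TTT, THT, TTH}→T, {HTT, HHH}→H;
  P2 {TTT, TTH, HTT}→TT&HT, THT→TH, HHH→HH; P3 {TTT, HTT, THT} pooled,
  TTH and HHH separate (27/18, 27/9/9, 27/9/9 animals at 9 per group).
  Unknown group labels pass through as their own pool.
- ADG = boundary-weight difference / interval length; F:G = total feed /
  total gain per animal, flagged undefined when gain ≤ 0 and excluded
  from the pool mean.
- Percent change is 100·(pre − during)/pre (positive = decrease),
  rounded half-away-from-zero when integer percents are reported.
- Day-12 body weight comes from the end-of-period weighing (= next
  period's day −3).

## Numerical details and limitations

- Overflow-safe softplus everywhere; smooth/sharp agreement is tested
  against the analytic kink envelope rather than a fixed absolute bound,
  since the envelope scales with |v1 − v2| (≈44 for intake vs ≈0.8 for
  temperature).
- The earliest-extremum convention and the contrast Y(hi) − Y(lo) are
  defined on the sharp limit; the smooth curve is still (weakly) moving
  near td2, so summaries on the smooth curve would shift by O(r).
- Degenerate inputs: σe² = 0 with replicated days is rejected; constant
  data initialise to a flat line; datasets need ≥3 distinct days per
  animal and ≥5 distinct days overall.
- Monte-Carlo scales: recovery experiments use 20 replicates of 18
  animals (12 days each); contrast power/type-I checks use 25 replicates
  of 9+9 animals with 2 optimizer starts.  These sizes mirror the source
  design while keeping the full suite under two minutes.
- Known limitations: single random intercept only; homoscedastic
  residuals; ML (no REML small-sample correction); Wald (not
  likelihood-ratio) contrasts; thresholds at a bound make the usual SE
  asymptotics approximate.
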