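# thermacclim

Biphasic acclimation modelling for heat-challenged growing pigs.

When finishing pigs are moved from thermoneutral conditions (22 °C) to a
multi-day heat challenge (32 °C), feed intake collapses and core body
temperature spikes within the first day; over the following days both
partially recover as the animals acclimate, before settling on a plateau.
`thermacclim` quantifies that biphasic trajectory with a smooth
broken-line model with two threshold days,

```
Y(d) = y0 + v1·d − r1·(v1 − v2)·ln(1 + e^{(d − td1)/r1})
             − r2·v2·ln(1 + e^{(d − td2)/r2})
```

where `d` is the day relative to challenge onset (day 0), `y0` the
response at day 0, `v1` and `v2` the linear rates before/after the first
threshold day `td1`, `td2` the day the curve reaches its plateau, and
`r1`, `r2` the widths (in days) of the smooth transitions.  As
`r1, r2 → 0` the curve tends to an exact piecewise-linear broken stick
with slopes `v1`, `v2`, `0` — used throughout as a verification oracle.

The model is fitted as a **nonlinear mixed model**: a per-animal random
intercept `b_i ~ N(0, σr²)` plus residual noise `ε_ij ~ N(0, σe²)`,
estimated by marginal maximum likelihood (the Gaussian intercept
integrates out in closed form; adaptive Gauss–Hermite quadrature is kept
as an independent cross-check).  Goodness of fit is reported as the
adjusted R² `1 − [SSE/(n−p−1)]/[CTSS/(n−1)]` on conditional
(empirical-Bayes) residuals.

The package is aimed at researchers analysing longitudinal
thermoregulation/feed-intake trials — or planning one: a synthetic
cohort generator reproduces a full 5-group × 3-period challenge design
(45 pigs, rooms rotating between thermoneutral and heated) from
published parameter presets, so fitting, power exploration and the
descriptive performance pipeline (interval ADFI/ADG/F:G, group pooling,
metabolic-weight scaling, percent-change summaries) are all testable
without animal data.

## Worked example

Simulate one cohort (18 animals, daily core temperature over days −1…10)
from the pooled first-challenge preset and refit it:

```python
import thermacclim as ta

data = ta.simulate_trajectories(ta.preset_from_table3("Tcore/P1"),
                                n_animals=18, seed=1)
fit = ta.fit_nlmm(data)
print(fit.summary())
```

```
Two-threshold acclimation NLMM fit (Tcore_C)
  n_obs=216  n_params=7  loglik=46.9315  adj.R2=0.8849
  sigma_r2=0.0124397  sigma_e2=0.0328728  converged=True
  group TTH&HHH: y0=39.29 (0.0366), v1=0.4548 (0.0323), v2=-0.3251 (0.0175), td1=1.613 (0.106), td2=6.18 (0.156)
```

The cohort was generated with `y0=39.3, v1=0.48, v2=−0.30, td1=1.46,
td2=6.30`: temperature rises 0.48 °C/d after the room heats up, turns
over at the first threshold day (≈1.5 d of exposure, the onset of
acclimation), declines 0.30 °C/d and plateaus from day ≈6.3.  The fit
recovers all five parameters within roughly one standard error, with an
adjusted R² of 0.88.  Sharp-limit summaries locate the features of the
fitted curve:

```python
s = ta.derived_summaries(fit.params_by_group["TTH&HHH"])
print(f"earliest minimum day: {s.earliest_min_day:.2f}")
print(f"temperature peak at td1: {s.extremum_value:.2f} degC")
```

```
earliest minimum day: 6.18
temperature peak at td1: 40.02 degC
```

The same workflow is available from a shell:

```sh
thermacclim simulate --preset Tcore/P1 --n-animals 18 --seed 1 --out cohort.csv
thermacclim fit cohort.csv --variable Tcore_C --period P1 --out-prefix fit_report
thermacclim simulate --study --seed 1 --out study.csv
thermacclim summarize study.csv --out performance.csv
```

`fit` writes a CSV/text report (per group: y0, v1, v2, td1, td2 with
standard errors, σr², σe², adjusted R²) and, for multi-group data,
pairwise Wald contrasts with compact letter groupings.  `summarize`
computes per-pool interval performance for the full study design.

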