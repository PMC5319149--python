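# Methods

## State space

Nine mutually exclusive alive states, ranked 1 (best) to 9 (worst): the DS3
severity band (mild, moderate, marked, severe) crossed with bone-disease
status. Bone pain (BP) is distinguished from "no bone symptoms" only within
the mild band; the other bands distinguish only the presence of severe
skeletal complications (SSC). The rank order is the ordinal outcome of the
transition regression. Death is an absorbing tenth state handled entirely
by the mortality model — it is never a category of the ordinal regression.

## Utilities

Utilities come from a linear (identity-link) regression of EQ-5D UK
utilities on severity contrasts (vs mild), bone pain, SSC, sex, and age at
treatment initiation, fitted by GEE to absorb repeated observations per
patient. Predictions use recycled predictions: with an identity link the
average of per-subject predictions equals the prediction at the sample
covariate means (prop. female 0.691, age 53.9), so each state's utility is
just the linear predictor there. Two conventions matter:

* the bone-pain coefficient is included for every SSC state, not only the
  mild+BP state, so the SSC penalty is `bone_pain + ssc = −0.080`;
* the age coefficient is published rounded to −0.002 with a wide CI; the
  package defaults to −0.0015 (inside the CI, rounding to the printed
  value), obtained by calibrating the mild-state prediction to the
  published utility range endpoints (0.76 mild, 0.52 severe+SSC). The
  printed −0.002 is selectable (`default_utility_coefficients("printed")`),
  shifting every utility down by ~0.027.

The Markov engine evaluates utilities at the estimation-sample means, not
at the simulated cohort's own demographics: the published
QALY-per-life-year ratios are consistent with the former. Utilities are
not censored at [0, 1]; a warning is raised if user-supplied coefficients
push a prediction outside.

## Transitions

One proportional-odds model drives all movement among alive states:
`P(rank ≤ k) = σ(cut_k − xβ)` with eight ordered cutpoints and a linear
predictor summing the previous-state contrast, the years-on-treatment
contrast (year 2, years ≥3 vs year 1), the baseline-severity contrast, and
−1.089 for an intact/residual spleen. The sign convention means larger
contrasts → stochastically worse next states; it is validated by the
dominance tests (intact spleens improve every cumulative probability) and
by the benchmark cells σ(0.740)=0.677 and σ(1.829)=0.862 for staying mild.
With all covariates categorical and fixed within a scenario cell, recycled
prediction and direct prediction coincide, so the 24 matrices (3 treatment
durations × 4 baseline severities × 2 spleen statuses) are computed row by
row from the category probabilities. The proportional-odds restriction is
retained as estimated; no partial-proportional extension is attempted.
Treatment duration is clamped: cycle 1 → year 1, cycle 2 → year 2, all
later cycles → years ≥3. For SSC-containing start states the baseline-D
covariate is the severity component (marked+SSC → D=marked).

## Mortality

Disease-specific mortality is a Gompertz hazard `h(x) = a·e^{bx}`. The two
parameters are identified by requiring the *spliced* curve to reproduce two
summary life expectancies — 68.0 years at birth and 42.29 remaining years
at age 32 — via 2-d root finding on (log a, b); convergence is verified to
1e-4 years and the calibration errors out with its residuals otherwise.
Splicing takes the elementwise maximum of disease-specific and
general-population annual death probabilities, because a Gompertz curve
fitted to reduced life expectancy falls below population mortality at high
ages (with the packaged table the crossover is in the 70s). One overall
curve is used for all cohorts regardless of spleen status, matching the
shared 42.29-year footprint of the published projections; the
spleen-specific life expectancies (64/72 years at birth) are available as
alternative calibration targets.

Life expectancy uses the half-interval convention
`e(x) = 0.5 + Σ_t S(x, t)`, crediting half a year in the year of death —
deliberately identical to the engine's half-cycle correction, so the
engine's person-years equal `e(start age)` exactly (transitions conserve
alive mass; a 20-random-matrix oracle test asserts equality to 1e-9).

The packaged general-population life table is **synthetic**: a
Gompertz–Makeham curve (A=2.0e-4, R=8.0e-6, α=0.11, ages 0–110, terminal
q=1) chosen once to give a UK-like life expectancy at birth of 80.7 years.
It lacks infant-mortality structure and cohort effects; any real life
table with the same `age,qx` CSV schema (e.g. a Human Mortality Database
export) can be substituted. The maximum age of 110 is an extinction bound;
occupancy beyond it is negligible for any realistic start age.

## Cohort engine

Cycle length is one year. Each cycle applies the age-specific death
probability uniformly across alive states (mortality depends on age only —
the estimated mortality data do not resolve it by health state), then
redistributes survivors with the scenario's matrix. Death-then-transition
versus transition-then-death differ at order q·Δp and are not separately
identified by the published description; the chosen order is fixed and
documented. QALY increments are half-cycle corrected
(`(start + end)/2` occupancy) and discounted at 3.5%/year with
start-of-cycle exponents `(1+r)^−(t−1)` — first-year benefits undiscounted,
the spreadsheet-model convention, which reproduces the published
discounted/undiscounted QALY ratio; end-of-cycle exponents are available
via `qalys(..., timing="end")`.

## Synthetic panels

The generator emulates the source study's design: default 130 patients,
follow-up drawn as round(Normal(13.3, 6.1)) clamped to [1, 25] years,
baseline states at the observed shares of the three most common states
(19% mild, 28% moderate, 28% marked+SSC, remainder uniform), 67.2% intact
spleens, per-patient sex (69.1% female) and age (Normal(53.9, 14), floored
at 18). State trajectories are sampled from the transition model itself;
utility observations take the regression's linear predictor at the
patient's own covariates plus Gaussian noise (sd 0.1, about the scale of
the fitted robust residuals), clipped to the EQ-5D UK range [−0.594, 1]
with the clip count logged. Two utility observations per patient mirror
the sparseness of the original quality-of-life measurements.

What the generator does *not* emulate: measurement error in DS3 scoring,
the SF-36→EQ-5D mapping noise, informative dropout, treatment switching,
and any violation of the proportional-odds assumption. Passing
parameter-recovery tests therefore show the estimators are correct for
data that follow the model, not that the model is correct for real
patients.

## Estimation

The transition model is fitted by proportional-odds maximum likelihood
(statsmodels `OrderedModel`, logit link, L-BFGS). Cluster-robust standard
errors use the sandwich `H⁻¹(Σ_g s_g s_gᵀ)H⁻¹` with patient-level score
sums and a G/(G−1) correction; cutpoint standard errors are mapped from
the optimizer's increment parameterization by the delta method. The
likelihood is exposed (`ordered_logit_loglike`) and verified against a
hand enumeration on a small panel. The utility model is a Gaussian GEE
with independence working correlation — point estimates equal OLS; the
robust covariance carries the clustering. Known limitation: with the
realistic state distribution, severe-band utility observations are rare
(~0.5% of rows), and few-cluster sandwich variances for that contrast are
understated, so "every coefficient within 2 robust SEs" recovery checks
fail by chance more often than the nominal 5% per term would suggest.

## Problem sizes and tolerances

Default projections run to cohort extinction (79 cycles from age 32).
Recovery tests use 500-patient panels (10 years, fixed follow-up) at
module level and a single 2000-patient panel for the end-to-end check;
these sizes put coefficient sampling error well inside the published
rounding of the parameter tables. Structural invariants (row-stochasticity,
mass conservation) are asserted at 1e-12; calibration targets at 0.01
years; quantities derived from rounded published coefficients at ±0.02
(utilities) or ±2% (QALYs, occupancy).

## Known limitations

* Untreated natural history, costs, adverse events, and treatment
  switching are out of scope; the framework compares treated cohorts only.
* The proportional-odds assumption is imposed, as in the source
  estimation, although it was reportedly not satisfied there.
* Projections for cohorts splenectomized before treatment are very
  sensitive to the large spleen coefficient (−1.089 logits): with the
  packaged parameter tables, splenectomized cohorts project markedly more
  time in moderate-or-worse states than intact cohorts, a larger contrast
  than some published projections show. The intact-cohort projections are
  the well-corroborated ones.
* The packaged life table is synthetic (see above); substituting a real
  table changes the calibrated Gompertz parameters but, by construction,
  not the two life-expectancy targets.
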