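# Methods

## The estimation problem

Multi-project camera-trap compilations record, for each project, two
comparison periods that differ in human activity but are otherwise as
similar as the contributors could make them. The package treats the
higher-human-activity period as the *treatment* and the lower one as
the *control*, regardless of calendar order, and estimates for every
project × species population the change in (a) the amount of activity
and (b) the timing of activity, then models the variation in those
effects across populations. The two stages are deliberately separated:
stage one needs only within-project data and produces an effect size
with a sampling variance; stage two treats those as known-variance
observations in a multilevel meta-regression, which is how heterogeneous
multi-project syntheses are conventionally pooled.

## Stage one

### Independent events and effort

Consecutive raw detections of one species at one station are chained
into a single independent event while each gap to the *previous raw
detection* is ≤ 30 min; a strictly larger gap opens a new event. The
window is a parameter (`window_minutes`); chaining from the previous
raw detection (rather than from the event's first image) follows common
camera-trap practice. Effort is the fractional-day overlap of each
deployment interval with the period — exact interval arithmetic, not
calendar-day counting. Period membership of an event uses half-open
intervals `[start, end)` so boundary events are never double-counted.

### Amount of activity

Per-station event counts `y` follow an NB2 model,
`Var(y) = μ + μ²/θ`, with

    log μ = β₀ + β₁·treatment + log(camera_days) + u_station,
    u_station ~ N(0, σ²)  (only when the same stations sampled both periods)

β₁ is the log detection-rate ratio. The likelihood is maximized by a
block-coordinate Newton scheme (regression block exactly, dispersion by
damped 1-D Newton); the station random intercept is integrated by a
Laplace approximation with the per-station modes found by vectorized
inner Newton — the same approximation glmmTMB uses, and agreement with
glmmTMB on frozen reference fits is within 1e-3 (tests/data/
nb_glmm_oracle.json). Standard errors come from the observed
information at the optimum; when σ → 0 hits its boundary, the flat
direction is profiled out before inverting. θ is capped at 1e6, the
Poisson limit; at the cap the β block still converges to machine
precision and its 2×2 information block provides the SE.

Populations with all counts zero are errors; populations where one
period has zero events stay in if the fit converges (their large
variance self-downweights downstream), and non-convergent fits are
excluded with a logged reason — the amount analysis has no
minimum-detection rule, so convergence is the documented inclusion
criterion.

### Timing of activity

Events are classed day/night by the sign of the geometric solar
altitude at the event start (NOAA low-precision ephemeris: Julian
centuries → declination and equation of time → hour angle → altitude;
verified within 0.2° — in practice ~0.012° — of an independently coded
reference grid). No atmospheric refraction: the day/night rule concerns
the geometric angle, and refraction shifts the terminator by under four
minutes. Altitude exactly 0 counts as day (a measure-zero tie).

The nocturnality index `N = night/(night+day)` is pooled over a
project's stations. For populations with ≥10 detections in both
periods the effect is `RR = ln(N_h/N_l)` with variance
`1/x_h − 1/n_h + 1/x_l − 1/n_l`; when any of the four cells (night or
day count in either period) is zero, 0.5 is added to every cell of both
periods — the conventional escalc-style correction, applied
symmetrically and only when needed.

### Orientation

The control/treatment orientation is decided by the sign of the fitted
human detection-rate coefficient — the same NB model with the same
effort offset used for animals, so orientation and effect sizes share
one effort correction. Projects without a camera-detectable change use
an expert override flag or are excluded. The detectability threshold
`min_effect` defaults to 0 (any nonzero estimate orients); tests use
1e-3 where exact equality of rates must be treated as "no signal"
despite optimizer-level noise.

## Stage two

Effect sizes `y_i` with known variances `v_i` follow

    y = Xβ + Z_p u_p + Z_f u_f + Z_s u_s + ε,  ε_i ~ N(0, v_i)

with independent variance components for project, family and
species-within-family (three components; family nesting stands in for
phylogenetic relatedness — no tree-based covariance). Variance
components are estimated by maximizing the profiled restricted
likelihood on log-variances (L-BFGS-B, bounds e^-30..e^5, three starts,
objective tolerance 1e-14); β = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with SEs from
(XᵀV⁻¹X)⁻¹ and z-based 95% CIs (β ± 1.96·SE). The REML log-likelihood
includes the +½ln|XᵀXᵀ| constant so values are directly comparable with
metafor's `rma.mv`; frozen reference fits agree within 1e-4
(tests/data/meta_oracle.json).

Model comparison uses **ML** likelihoods whenever fixed-effects
structures differ (REML likelihoods are not comparable across fixed
effects), with the reported model refit by REML. AICc counts fixed
coefficients *and* variance components as parameters. Candidate terms
screened against the global model: HMI × openness, trophic group × HMI,
trophic group × openness, HMI². A candidate is *supported* when it is
within 2 AICc of the best model and beats the simpler nested global
model; the retained model is the AICc-best. Moderators with incomplete
data (hunting status, relative brain size, camera-measured human fold
change) are screened on their complete-case subsets against the global
model refit on the same subset, reported only when they lower AICc.

Heterogeneity uses the multilevel I² with the typical sampling variance
`ṽ = (k−1)Σw / ((Σw)² − Σw²)`, `w = 1/v`; each level's I² is its share
of (Σσ² + ṽ) and the total is the sum. Pseudo-R² is the proportional
reduction in summed variance components against the intercept-only
model, floored at 0. Continuous moderators are z-scored (sample SD)
with the scaling stored; reference levels are diel = diurnal, trophic
group = large herbivore, openness = closed, comparison = between-year,
so the intercept is a diurnal large herbivore in closed habitat under a
between-year comparison. Percent changes are
`100·(exp(Δŷ) − 1)` along one predictor with the others at reference.

## The synthetic-data generator

`simulate_counts` draws the statistical skeleton: per-population true
effects `β = β̄ + u_project + u_family + u_species + Σ slope·moderator`
(slopes act on centred moderators so the population mean stays β̄),
NB2 per-station counts around effort × rate, and binomial night counts
whose treatment probability is `N_l·exp(rr)` — the shift is
parameterized directly on the risk-ratio scale to match the estimand,
clipped to (0.01, 0.97). `simulate_study` materializes the skeleton
into timestamped detections: event times are placed uniformly inside
the day or night solar window of a random in-period date (2-minute
margin from the terminator), spaced >30 min apart within
station × species so event building recovers the drawn counts exactly;
human detections are Poisson with a configured fold change; research
personnel and a domestic species are added at low rates to exercise the
filters. One `numpy` Generator keyed by `seed` drives every draw in a
fixed order, so all tables are byte-reproducible from (config, seed).

Defaults are the scale used throughout the tests: 10 projects × 15
species × 10 stations, 60-day periods, lognormal baseline rates around
0.15 events/day (sdlog 0.6), θ = 2, random-effect SDs
(0.2, 0.1, 0.15), baseline nocturnality 0.35, human fold changes
1.5–8×. Latitudes are restricted to ±55° (validated up to ±66°) so day
and night windows exist year-round. What the generator does *not*
emulate: spatial autocorrelation between stations, camera failures
inside deployments, seasonal drift in activity within a period,
station-level abundance heterogeneity beyond NB overdispersion, and
imperfect species identification — so passing recovery tests show the
estimators are correct under the model's own assumptions, not that
those assumptions hold in any particular field dataset.

## Validation experiments and problem sizes

`wildshift.validation` runs the Monte-Carlo experiments used by the
test suite and `scripts/acceptance.py`:

- *recovery*: 200 replicates at the default scale with true mean
  effects −0.3 (amount) and +0.1 (timing); checks |bias| < 3 MC SE and
  95% CI coverage within [90%, 98%]. These replicates use the count
  skeleton directly and the fixed-effects NB path (the generator draws
  no station-level heterogeneity; the random-intercept path is
  validated against the frozen glmmTMB references instead), which keeps
  the experiment at desk scale.
- *selection power*: 100 replicates with a planted carnivore × HMI
  slope of 1.6 on the centred-HMI scale. The slope was calibrated (on a
  dedicated calibration seed, separate from the test seeds) to the
  experiment's design target of comfortably ≥ 80% recovery: the
  trophic × HMI candidate adds five parameters (a six-level factor
  crossed with HMI), so its AICc hurdle is ≈ 10 likelihood units, and
  HMI varies only between the 10 projects — a planted interaction must
  be strong to clear that bar. A replicate scores when the
  trophic × HMI candidate attains the lowest AICc.

With ~10 projects, z-based intervals with REML variance components are
expected to sit at the low end of the coverage band (~90–93%); this is
the standard behaviour of Wald intervals in multilevel meta-analysis
and is the convention the pipeline reports.

Two small systematic effects of the specified estimators are visible at
Monte-Carlo precision and worth knowing about. The pooled log risk
ratio carries a slight positive bias (of order +0.01 at these
population sizes): the plug-in sampling variance of RR shrinks as
nocturnality rises, so more-nocturnal populations receive more weight,
and the log of a binomial proportion is itself biased downward more for
the smaller proportion. Both are inherent to inverse-variance pooling
of risk ratios, not to this implementation. The pooled log rate change
shows no measurable bias.

## Numerical choices and edge cases

- NB dispersion capped at θ = 1e6 (Poisson limit), log-variance bounds
  e^-7..e^3 for the station SD; convergence judged by the projected
  gradient when the line search stalls on a flat dispersion direction.
- Meta σ² snapped to 0 below 2e-13; singular designs raise with the
  collinear columns named.
- Timestamps must carry explicit UTC offsets; coordinate-based timezone
  lookup is intentionally out of contract.
- Domestic animals are excluded by an `is_domestic` flag (data, not a
  curated taxonomy); species are matched to traits by
  whitespace/case-normalized exact names, with unmatched species warned
  and dropped.
- Body-mass classes split at exactly 20 kg with the boundary assigned
  to "large"; species below 1 kg are excluded before trophic grouping.

## Known limitations

Stage one treats stations as independent; there is no occupancy-style
detection model, no zero-inflation, and no activity-overlap (kernel
density) metric. Stage two has no full phylogenetic covariance and no
robust/clustered variance option. The period endpoints are inputs —
changepoint detection on the human detection series is out of scope.
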