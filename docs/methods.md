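# Methods

This note records the models, conventions, numerical choices and known
limitations behind `budburst`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Transition encoding

Bud trajectories are ordinal and must be non-decreasing; validation
reports stage regressions and duplicate censuses, and the lenient mode
drops offending buds (counted in the run log). Stages 1 and 2 are merged
to a single label `12` before encoding.

For transition k→m the default **strict** risk set contains, per bud,
every census at exactly stage k (outcome 0) and the first census at or
beyond m (outcome 1). Records before the bud reaches k and after its
first success are excluded; a census that jumps several stages is the
success record of every transition it completes; a bud already at or
beyond m at its very first census was never observed at risk and
contributes nothing. Because the field protocol's exact risk set is a
reconstruction, a **cumulative** mode (all records from the first census
to the first success, outcome = 1(stage ≥ m)) is kept as a documented
alternative; both are covered by a brute-force re-encoder property test.

## Covariates

* **GDD**: cumulative Σ max(T − 0 °C, 0) from DOY 1, truncating at the
  daily level (the standard degree-day convention), from tmean
  (`gdd_mean`) and tmax (`gdd_max`). Gaps must be filled first; the
  accumulator refuses gapped series, naming the missing days.
* **Frost probability**: logistic regression of the daily indicator
  1(tmin < 0 °C) on DOY. "Below 0 °C" is read strictly: tmin = 0.0
  codes 0. The default fit pools years within a site (a per-(site, year)
  flag exists) and uses the spring record from DOY 90 onward, emulating
  temperature loggers deployed at snowmelt; the mid-winter plateau of
  daily frost probability ≈ 1 would otherwise distort the fitted spring
  slope. Degenerate inputs (one outcome class, complete separation)
  yield a flagged, clamped model rather than an error.
* **Day length**: sunrise-equation hours with sun altitude −0.833°
  (refraction plus half solar disc). Declination follows the NOAA solar
  calculator (mean longitude/anomaly, equation of center, apparent
  longitude, corrected obliquity) anchored to a nominal fixed year, so
  day length is a function of latitude and DOY alone. Polar latitudes
  (|lat| > 66°) are rejected. An independently coded Meeus-style oracle
  agrees within 2 minutes for |lat| ≤ 60°.
* **Gap filling**: per logger and variable, OLS of observed on reference
  over ≥3 overlapping days; missing days are predicted, predictions
  averaged over loggers, and spliced — observed days are never altered.
  Regressions with p ≥ 0.05 warn and are excluded from averaging.
* **Standardization**: z-scores with stored (mean, SD) per variable,
  fitted season-wide on the pooled covariate table. The generator uses
  the same scope, so fitted coefficients are directly comparable to the
  generating ones, and stored parameters are reapplied to
  prediction-time covariate paths.

## Mixed-model fitting

The logit model with crossed random intercepts u_f ~ N(0, σ_f²) (year,
tree) is fitted by a Laplace approximation in the spherical
parametrization: ℓ(β, σ) ≈ ℓ_cond(β, û) − ½û'û − ½ log|Z̃'WZ̃ + I|,
with û from a damped Newton (penalized IRLS) inner solve. Because all
random terms are intercepts, each factor's Hessian block is diagonal;
the inner systems eliminate the largest factor analytically and solve a
small Schur complement, making the cost linear in records and levels.

Two outer stages mirror lme4: a profiled stage optimizes log σ alone
with (β, u) solved jointly inside (nAGQ = 0), then the default **full**
stage optimizes (β, log σ) together (Nelder–Mead for ≤4 parameters,
L-BFGS-B with numeric gradients above). Three starting values are
screened; a failed optimization is retried from perturbed starts and
otherwise flagged — never silently returned. log σ is bounded in
[−6, 3]; estimates at the lower bound are boundary fits (σ² ≈ 0),
reported as such. Standard errors for β come from the fixed-effect block
of the inverse joint penalized Hessian, which propagates uncertainty in
u. On identical data the fitter matches `glmer` (bobyqa, Laplace) to
about 1e-4 in coefficients, variance components and log-likelihood
(tested against Rscript/lme4).

The **fast** preset stops after the profiled stage. It attenuates β by a
few percent (the log-determinant's β-dependence is ignored) but leaves
coefficient *ratios* — hence threshold crossings — essentially unchanged,
so large candidate sweeps use it; each phase winner can be refitted with
the full scheme (`refit_best`).

k for AICc counts fixed effects plus one variance component per retained
random factor (common mixed-model practice; the convention is stated
because alternatives exist). Non-converged candidates are excluded from
ranking, not assigned infinite AICc. Pseudo-R² is Nakagawa–Schielzeth
for the logit link: R²m = σ²_f/(σ²_f + Σσ²_re + π²/3) with σ²_f the
variance of the fixed-effect linear predictor over the fitted records.
Coefficient "significance" is |β| > m·SE with m = 1.96 by default and
configurable (m = 1 reproduces a bare ±SE rule).

## Candidate sets and two-phase selection

Each candidate carries a single climate variable V in one of five
structures — {V}, {V+site}, {V+group}, {V+site+group}, and the full
two-way set {V+site+group+V:site+V:group+site:group} — plus one
day-of-year null per pool: 6 temperature variables → 31 models, 1
photoperiod variable → 6. The compositions are a reconstruction that
matches those counts; the enumeration is data-driven so an explicit list
can be substituted via the pools. Selection runs in two phases
(temperature, then photoperiod); the winners are compared by the
magnitude of their standardized climate coefficients, and a
weight > 0.05 plausible set triggers natural model averaging.

## Prediction

Transition curves are population-level (random effects at zero) on a
daily covariate path standardized with the training parameters.
The crossing is the **first upward** crossing of the 0.51 threshold
(configurable), linearly interpolated between bracketing days — curves
driven by frost probability need not be monotone in DOY, and weekly
field resolution does not warrant a continuous-time root solve. A curve
never reaching threshold yields a `no_crossing` status, not an error;
negative durations are flagged `ordering_anomaly` (separate per-
transition models can predict late stages before early ones). Heating
requirement interpolates the cumulative GDD series at the crossing; per
the field convention it is evaluated at the bud-open (4→5) crossing.

## Synthetic study

The generator emulates a two-plantation transplant design. Site
climates: temperate (lat 47.29°, MAT 3.1 °C, amplitude 16.9 °C) and
boreal (lat 48.29°, MAT 1.0 °C, amplitude 17.3 °C) — the printed
normals of the two stations nearest the plantations — with temperature
peak at DOY 201, diurnal range 18 °C, and AR(1) tmean noise
(ρ = 0.6, innovation SD 3.0 °C) plus independent tmin/tmax noise,
clamped to tmin ≤ tmean ≤ tmax. The diurnal range is set high to mimic
radiative night frosts, placing the fitted frost probability near 0.4
at the first-transition crossing and the temperate 0.10-probability
date near DOY 166, as the study area's normals describe; the boreal
frost season then ends 1–3 weeks later depending on the draw.

Bud development is a daily Bernoulli hazard (at most one stage advance
per day, matching the weekly census granularity): logit h = β₀ + β₁·x(d)
+ σ_tree·z_tree + σ_year·z_year, with z drawn once per tree and per
(site, year) from split deterministic seed streams (weather /
random-effects / hazard are independent streams of one master seed).
Default drivers: frost probability for 0→12 and 12→3, GDD-mean for
3→4, 4→5, 5→6. Intercepts are calibrated so the noiseless hazard
crosses 0.51 at target days (white-spruce analogue 140…161, black-spruce
analogue 145…165 at the temperate reference site-year, inside the weekly
census window DOY 130–185) with a logit slope of 1.2/day; σ_tree = 0.5,
σ_year = 0.3; 50 trees per group per site × 2 groups × 4 buds × 2 years.

**Ground-truth crossings.** A binomial model fitted to weekly censuses
estimates the per-census-interval transition probability, not the daily
hazard, so the generator records two noiseless crossings per
(site, year, group, transition): the daily hazard's own 0.51 crossing
and the crossing of the census-interval-aggregated probability
1 − Π(1 − h) over a sliding window of the census spacing. End-to-end
recovery is judged against the interval-aggregated truth — the quantity
the fitted curve actually estimates.

What the generator does **not** emulate: sub-daily microclimate and
frost pockets, snow, bud mortality, chilling/dormancy dynamics,
photoperiod-driven transitions (day length is available as a driver but
the default scenario does not use it — its candidates compete as
proxies), and observation error in stage scoring. Passing tests
therefore show that the pipeline recovers known drivers and dates under
the modelled census process, not that the field data satisfy the model.

## Problem sizes and presets

The end-to-end recovery study runs 20 replicates of the full design
(2 sites × 2 years × 100 trees × 4 buds, weekly censuses) with the fast
Laplace preset and no winner refit — crossings are ratio quantities and
are unaffected by the fast stage's proportional attenuation. The Wald
coverage check uses 100 replicates of 4 000 records with 200 trees and
the full scheme. The acceptance script runs one full-design replicate.

## Known limitations

* The exact candidate-model compositions behind the printed counts are
  reconstructions; swap in explicit pools via configuration if known.
* AICc's k for mixed models is convention-dependent (see above).
* Laplace marginal likelihoods for binary data are approximate; variance
  components of 2-level factors (year) are weakly identified, and a
  small positive estimate on data generated without a year effect is
  expected ML behaviour, not a defect.
* Corner cells of the design (the latest group at the colder site, near
  the end of the census window) carry the least risk-set information;
  their predicted crossings are the least accurate and can show the
  ordering anomalies the per-transition modelling permits.
* Model-selection uncertainty beyond Akaike weights, random slopes, and
  parametric-bootstrap intervals on crossing days are out of scope.
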