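# Methods

## The performance model

Larval growth is summarized as a specific (log-scale) rate,
`g = (ln(final head width) − ln(initial head width)) / days`, in units of
day⁻¹. Head width (mm, outer eye margin to outer eye margin) is the body-size
proxy throughout. The temperature dependence of `g` is modelled with the
O'Neill (1972) thermal performance curve

    rate(T) = R_max · ((CT_max − T)/(CT_max − T_opt))^x
                    · exp(x · (T − T_opt)/(CT_max − T_opt))

with `w = (Q10 − 1)(CT_max − T_opt)` and, in the canonical form used by
default, `x = (w²/400)(1 + √(1 + 40/w))²`. The curve satisfies
`rate(T_opt) = R_max` and `rate(CT_max) = 0` identically, is unimodal with
its single peak at `T_opt`, and has no lower critical limit — rates decay
smoothly toward zero with falling temperature. Above `CT_max` the base term
turns negative and a non-integer power would be complex; the implementation
defines the rate as exactly zero there, the biologically meaningful
continuation.

A second variant of the exponent, `x = (w²/400)(2 + 40/w)` (the "literal"
form, equivalent to placing the square inside the radical), appears in some
typeset renditions of the model. Both are implemented behind an `x_form`
switch (`canonical` default); they produce visibly different curvature
(x ≈ 12.65 vs 6.63 at the reference parameters), so the choice is exposed
rather than silent.

A note on units: the growth-rate formula yields a log-scale rate (day⁻¹),
although `R_max` for this system is conventionally printed as "mm day⁻¹".
The package carries day⁻¹ internally and makes no attempt to reconcile the
printed label.

Reference parameter set (package-wide default, `REFERENCE_TPC`): R_max = 0.0681
day⁻¹, T_opt = 26.9 °C, CT_max = 44.7 °C, Q10 = 2.56 — the published point
estimates for *Enallagma cyathigerum* larval growth.

## Fitting

`fit_oneill` minimizes the sum of squared rate residuals with bounded
trust-region least squares (`scipy.optimize.least_squares`, `trf`,
ftol 1e-10, xtol 1e-8). Start values are data-driven: the start optimum is
the temperature with the highest mean observed rate (lowest such temperature
on ties), the start `R_max` that mean, start `CT_max` the warmest rearing
temperature + 15 °C, start Q10 = 2. Ten seeded restarts from ±20% uniform
jitters of the start vector guard against the local minima of peaked TPCs;
the best residual sum of squares wins. Default bounds: R_max ∈ (0, 10·max
observed rate], T_opt ∈ [min temp, max temp + 20], CT_max ∈ (min temp,
max temp + 40], Q10 ∈ (1, 10]. At least four distinct temperatures are
required (four free parameters).

Uncertainty is by case-resampling bootstrap (resample observations with
replacement, refit, percentile interval). **Caveat:** with all five design
temperatures (17–28 °C) left of the ~27 °C optimum, `CT_max` is weakly
identified at realistic noise; its intervals are expected to be wide, and
tests do not assert tight `CT_max` recovery under noise. Noise-free data on
this design do identify all four parameters (recovered to ≤1e-4 relative
error), which is the basis of the generate-and-refit checks.

## Temperature regimes

Fluctuating treatments are symmetric trapezoidal waves: the heater set point
alternates between the band minimum and maximum every half cycle (7 days for
the default two-week cycle), and each switch is followed by a linear ramp of
12 h — the approximate time the water bath needs — then a hold. The "weekly
fluctuating" description is read as weekly set-point changes, i.e. 7-day
half-cycles, consistent with "three full cycles = six weeks" (single
experiment) and "four full cycles = eight weeks" (interaction experiment).
Because up- and down-ramps have equal length, the time mean is exactly the
band midpoint for any ramp length; the four treatments (constant 23, 22–24,
21–25, 20–26 °C) therefore share a 23 °C mean. Profiles start at the
beginning of a warm half cycle (set point at the maximum, temperature
ramping up from the minimum); phase and ramp shape are configurable (a
sinusoid can be compared by supplying a custom profile). The default grid is
1 h; Jensen analyses should not use coarser grids, since the trapezoid
integral is exact only while switch and ramp-end times fall on the grid.

## Jensen's inequality

For a nonlinear performance curve, mean performance under a fluctuating
temperature differs from performance at the mean temperature. `jensen_gap`
computes (time-average of `rate` over the profile, trapezoid rule on the
profile's native grid) − (`rate` at the profile's time-mean temperature).
Constant profiles give exactly zero (short-circuited, not merely ≈0), and
affine rate functions give zero for any profile — both are tested. Just
below the optimum the curve is concave over the excursion range, so the gap
is negative: the below-mean secant slope (20→23 °C, 0.00679 day⁻¹ °C⁻¹ at
the reference parameters) exceeds the above-mean slope (23→26 °C,
0.00494), and the widest band (20–26 °C) loses about 5% of the rate at the
mean — a real but small predicted deficit.

## The synthetic cohort generator

No raw experimental tables ship with the package; an individual-based
simulator generates data with the statistical structure the analyses assume.
Per treatment arm: 10 containers × 10 larvae over 56 days (the experimental
design). Daily, per container:

1. every live larva grows multiplicatively,
   `hw ← hw · exp(rate(T_day) + ε)`, `ε ~ N(0, growth_noise_sd)`, where
   `T_day` is the regime temperature at noon;
2. each live larva dies intrinsically with probability `intrinsic_hazard`
   (developmental failure — leaves a carcass);
3. pairwise encounters are Poisson with mean
   `encounter_rate_ref · activity_q10^((T_day−23)/10) · n(n−1)/90` (so a
   full container of 10 at 23 °C sees the reference rate); distinct pairs
   are drawn uniformly; an encounter kills the smaller larva iff the
   larger-to-smaller head-width ratio is ≥ the threshold ρ. Cannibalized
   larvae vanish without a carcass — the "missing larvae" proxy.

Weekly censuses record live counts and carcasses accumulated since the last
census. Initial sizes are lognormal with configurable mean and CV
(positivity guaranteed, variance tunable for the size-variance analysis).
The ratio direction is implemented as cannibal/victim ≥ ρ (larger eats
smaller), the standard size-structured convention; the alternative reading
("victim-to-cannibal ratio exceeds a critical value") is the same criterion
with the reciprocal threshold.

Mechanism parameters are *synthetic calibration constants*, not estimates:
no study reports encounter or hazard rates. They live in
`thermvar/calibration.py` and were fixed once so that a default
four-treatment run loses roughly two thirds of its larvae to cannibalism
(the qualitative attrition shape of the emulated experiment): reference
encounter rate 2.5/container/day, ρ = 1.15, growth noise 0.01 day⁻¹,
intrinsic hazard 5e-4 day⁻¹, initial-size CV 0.10, activity Q10 = 2.

What the simulator does *not* emulate: instar/moult structure, food
dynamics (feeding is ad libitum), within-container space or refuges, and
any feedback of density on growth. Passing tests therefore demonstrate that
the analysis pipeline recovers known mechanisms from data of this structure
— not that real damselfly data have these mechanisms. With the reference
TPC driving growth, simulated eight-week size increases are larger than
realistic head-width gains (a consequence of taking the published rates at
face value on the log scale); this affects none of the rank/threshold
mechanics the analyses test.

## Statistics

* **Cannibalism bookkeeping**: per container, cannibalized = initial − final
  alive − total carcasses; carcasses are intrinsic mortality and excluded
  from cannibalism. Impossible books (carcasses exceeding the count
  decrement) raise a data error naming the container.
* **One-way fixed-effects ANOVA**: textbook sums-of-squares decomposition,
  F = MS_between/MS_within on (k−1, N−k) df. Applied to binary mortality
  indicators exactly as in the original analysis (0/1 treated as
  continuous) — fidelity over orthodoxy. Degenerate all-identical input is
  defined as F = 0, p = 1.
* **Binomial GLM**: logit link, fit by IRLS via statsmodels (tol 1e-10,
  ≤100 iterations); the treatment test is the likelihood-ratio deviance
  chi-square (null − residual deviance on levels−1 df). For this saturated
  one-factor model fitted probabilities equal group survival proportions,
  and the statistic is invariant to level relabelling. Complete separation
  is flagged with a warning; the deviance is still reported.
* **Tjur's r²** (coefficient of discrimination): mean fitted probability in
  the event group minus that in the non-event group.
* **Size-variance regression**: OLS of log(cannibalized + 1) on √(initial
  head-width variance). The +1 offset (configurable `log_offset`) handles
  zero counts, which the source analysis leaves unspecified. A constant
  response is defined as slope 0, r² 0, p 1. The shipped report aggregates
  per container (one point per container); the function accepts any aligned
  vectors, and the report states the aggregation used.
* The description of the size-variance analysis as "logistic regression
  using the lm function" is internally inconsistent; the implemented model
  is the transformed linear regression its transformation sentence
  describes.
* p-values are two-sided; α = 0.05 is reported, never used to gate
  computation. No multiple-testing correction is applied (none was in the
  original analysis).

## Problem sizes and numerical conventions

Generate-and-refit checks use the five-temperature design with 20
observations per temperature. The noisy-recovery study is 100 replicates at
noise sd = 10% of R_max (a Monte-Carlo run whose observed success count,
97/100 optima within ±1 °C, is frozen as a ≥90/100 regression bound). The
size-variance and warm/cold-activity Monte-Carlos use 200 containers per
arm. Floating-point equality in tests is asserted at relative tolerance
1e-9 unless an operation states otherwise; frozen curve constants were
computed symbolically to 20 significant digits.

## Known limitations

* `CT_max` extrapolates ~17 °C beyond the warmest design temperature; treat
  its point estimate and intervals accordingly.
* The simulator's mechanism constants are calibration choices; simulated
  magnitudes (deviances, r² values) are not comparable to published
  magnitudes — only directions and structural properties are.
* The trapezoid regime is an idealization of a heated water bath; measured
  bath profiles can be supplied as CSV (`hours, temp_c`) wherever a
  generated profile is accepted.
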