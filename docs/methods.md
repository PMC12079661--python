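# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `aviphen`. It is the design record for maintainers; the
tests and `scripts/acceptance.py` compute everything quantitative claimed
here.

## 1. The measurement problem

A bird in a ventilated chamber depletes O₂ and adds CO₂ and water vapor to
the outflowing air. With chamber volume *V* and pull flow *FR*, a perfectly
mixed chamber responds to any change in gas exchange as a first-order system
with time constant τ = *V*/*FR*; for the reference geometry (13 l at
1700 ml min⁻¹) τ = 7.65 min, i.e. 63.2 % of chamber air is replaced per τ.
(Published descriptions of this rig round the same quantity to 7.5 min; the
package computes 13000/1700 and exposes `ChamberConfig.effective_tau_min`
for users whose effective mixing volume differs from the geometric one.)

Because one analyzer chain serves many chambers, a multiplexer samples each
chamber for 60 s and an ambient baseline for 60 s per cycle: seven chambers
plus baseline gives a 480 s cycle, one metabolic point per bird per 8 min.

## 2. Gas processing chain

Order of operations (each is a public function in `aviphen.respirometry`):

1. **Lag alignment.** The O₂ analyzer sits further downstream than the
   CO₂/H₂O bench; channels are shifted earlier by fixed transit lags
   (defaults 7 s and 5 s, from configuration, not flow-adaptive).
2. **Per-dwell smoothing + instantaneous correction.** Within each marker
   run, channels get a 5 s centered moving average and the O₂ channel the
   z-transform *F* + τ·d*F*/d*t* (central differences on the smoothed
   series, one-sided at segment ends). Applying it per dwell keeps the large
   derivative at multiplexer switches from contaminating neighboring slots.
   The correction is exact on exponentials up to discretization (the
   central-difference factor sinh(Δ/τ)/(Δ/τ) ≈ 1 + (Δ/τ)²/6, negligible for
   τ ≫ 1 s). Only O₂ is corrected, matching the acquisition macro this
   reimplements; CO₂ and H₂O therefore carry the full chamber lag.
3. **Stable windows.** For each dwell, the contiguous sub-segment covering
   50 % of the final 30 s with the minimum O₂ standard deviation is chosen
   by exhaustive scan (ties → earliest); all channels are averaged over it.
   The commercial software's exact stability criterion is unpublished;
   contiguity + minimum SD is the simplest faithful reading.
4. **Water-vapor dilution correction.** Dry fraction = wet / (1 − WVP/BP),
   dry flow = flow · (1 − WVP/BP). Mathematical drying replaces chemical
   desiccants; the round trip is exact.
5. **Baselining.** Chamber-window values minus the linear time interpolation
   of the bracketing ambient-window values, per channel (edge windows use
   the nearest single baseline). Linear interpolation cancels any affine
   analyzer drift exactly; slower-than-affine drift cancels to second order
   over the 8 min between baselines. Following the acquisition macro, drying
   precedes baselining.
6. **Pull equations.** With the flow metered on the dried excurrent side and
   both gases measured, nitrogen conservation fixes the incurrent flow:
   FRᵢ = FRₑ(1 − FeO₂ − FeCO₂)/(1 − FiO₂ − FiCO₂), then
   V̇O₂ = FRᵢFiO₂ − FRₑFeO₂ and V̇CO₂ = FRₑFeCO₂ − FRᵢFiCO₂. Incurrent dry
   fractions come from calibration constants (0.2095 / 0.0004); excurrent
   fractions are ambient plus the baselined deltas. V̇H₂O converts the
   baselined dry-basis mixing ratio r = WVP/(BP − WVP) by
   V̇H₂O = FRₑ·Δr·(18.02 g mol⁻¹ / 22.414 l mol⁻¹); it is reported
   uncorrected for fecal/spilled water. These are the standard mass-balance
   forms for this plumbing; the source protocol cites them without printing
   equations, so they are spelled out here and in the code.

**Energetics.** Rates integrate to hourly/daily totals by trapezoid with
linearly interpolated virtual points at bin boundaries, so daily totals equal
the sum of hourly totals by construction; bins with no points carry no value
and bins covering less than 50 % are flagged. EE uses the protein-free Weir
conversion, EE[kcal] = 3.941·V̇O₂[l] + 1.106·V̇CO₂[l], in kJ (×4.184) —
stated prominently because labs differ in Weir variants. Daily minimum MR is
the mean of the two lowest V̇O₂ points per experiment-clock day (midnight
boundary by default, shiftable via `offset_s`; the protocol does not state
whether its 24 h windows anchor to midnight or lights-on).

## 3. Load-cell pipeline

1 Hz perch/food/water channels → 60 s centered rolling mean and SD →
per-600 s block, keep the mean with the lowest SD (ties → earliest; blocks
without one complete window are skipped). A centered window is used because
it has no phase shift; the source protocol does not specify the alignment.
This is a ~600-fold data reduction per channel.

Consecutive stable points are differenced within tare-delimited segments
(taring re-zeroes accumulated drift every couple of days; differencing across
a tare would fabricate a step). Each delta carries the propagated error
√(sd᎐² + sd₊²). The 3-SD outlier rule removes deltas more than 3 empirical
SDs from the per-channel mean; the mean and SD are computed over
**sub-threshold** deltas (|Δ| ≤ 20 g) only. Rationale: refill (~+150 g) and
dish-sleeping (~±27 g) deltas have their own dedicated rules below, and if
they entered the outlier statistics they would either be swallowed by the
outlier rule before classification or inflate its SD to meaninglessness —
the only self-consistent ordering classifies the large deltas by rule and
applies the stability filter to the rest.

Classification on food/water deltas: |Δ| in (20, 35] g → body-mass recode of
|Δ| grams (step-on and step-off directions both kept, flagged by sign);
|Δ| > 35 g (and any other super-threshold delta, e.g. a positive refill
step) → refill/perching exclusion; remaining deltas → consumption. Intake
per bin sums the negative consumption deltas (net summation is available via
`ProcessingOptions.intake_net` for users who want spill-back credited).
Body mass per bin averages perch stable points within a plausibility band
(default 15–45 g, to exclude empty-perch readings) and the recoded dish
events. The empty-chamber diagnostic `sensor_drift` reports daily
max − min per channel.

## 4. The simulator (study conditions)

The digital twin generates every raw stream from known truth. Defaults are
the reference campaign: 3 birds in a 7-chamber system, 10 days, 12:12
lights (on 07:00–19:00), daily temperature steps 25 → 5 °C.

**Metabolism.** V̇O₂ = a(t)·BMR + c·max(0, LCT − Tₐ): Scholander-type
piecewise-linear thermoregulation, flat at thermoneutrality. The circadian
activity factor a(t) (1.2 lights-on, 1.0 lights-off) scales the basal term
only, so the marginal EE–temperature slope is a(t)-independent and equals
c·k(RQ), where k(RQ) converts ml O₂ min⁻¹ sustained for an hour into kJ via
Weir (1.23 kJ per ml min⁻¹ at RQ 0.85). An alternative form multiplies the
whole expression by a(t); that couples the circadian factor into the thermal
slope and makes "the generator's EE–temperature slope" ill-defined, so the
additive form was chosen — physiologically it amounts to thermoregulatory
heat production adding to, rather than scaling with, activity metabolism.
Defaults: body mass 27 g, BMR 1.4 ml O₂ min⁻¹, LCT 25 °C, RQ 0.85;
conductance defaults to the value giving an hourly-EE slope of 0.05 kJ °C⁻¹
(`conductance_for_ee_slope`), the thermal response reported for this system.
BMR and a slow biological variability term (lognormal AR(1), log-SD 0.06,
40 min correlation, unit mean) were chosen together so the daily
two-lowest-V̇O₂ statistic of the default bird at 25 °C lands in the
1.0–1.6 ml min⁻¹ range expected for house-sparrow-sized passerines: the
order statistic sits systematically below the basal mean, so larger or
faster noise would push it out of the basal range.

**Evaporative water.** V̇H₂O = 3.5 mg min⁻¹ · 1.05^(Tₐ−25) · 0.96^(RH−50) ·
AR(1) noise: +5 %/°C and −4 %/%RH multiplicative responses matching the
log-linear model this system's data support, anchored at a realistic
mid-range loss rate.

**Chamber and analyzers.** Wet outlet fractions relax toward the
instantaneous pull-mode steady state by the exact zero-order-hold exponential
update (never Euler), so simulated step responses match 1 − e^(−t/τ) to
machine precision and mass balance closes analytically. Chambers start at
equilibrium (birds are resident before recording starts). The multiplexed
trace then passes through transit delays (7/5 s), a first-order analyzer
response (τ = 3 s, 10–90 % step time 6.6 s — under the 7 s instrument
spec), additive Gaussian noise (1 × 10⁻⁶ fraction units for O₂ and CO₂,
0.002 kPa for WVP — instrument-grade resolutions) and linear span drift
(1 × 10⁻⁵ h⁻¹ O₂), which the interleaved baselines exist to cancel.

**Environment.** Daily setpoints with a first-order air-temperature response
(τ = 600 s — environmental chambers do not step instantaneously) and RH as
a linearly interpolated hourly AR(1) (mean 50 %, SD 5, φ = 0.7) independent
of the temperature program. Earlier development versions used
piecewise-constant RH and instantaneous midnight steps; the resulting
discontinuities are physically unrealistic and they propagate into the
τ-amplified derivative term of the z-transform.

**Intake and behavior.** Hourly targets during lights-on:
food = 5.7/12 + 0.1·(EE_h − 2.0) g (clipped at 0, Gaussian hour noise
SD 0.05 g) and water = 9.4/12 · 1.17^(EE_h−2.0) g (lognormal hour noise,
log-SD 0.08), where EE_h is that hour's true EE in kJ — compensatory
feeding/drinking coupled to concurrent energy expenditure, with baselines
reproducing daily intakes of ≈5.7 g food and ≈9.4 g water at the reference
EE. Within an hour the mass leaves the dishes as a quasi-continuous trickle:
a sparrow removes ~0.5 g h⁻¹ of ground diet in well over one peck per
minute and water in small licks, which a 60 s rolling filter sampled per
10 min cannot distinguish from a smooth decline. This matters: the 3-SD
delta filter measures the dispersion of per-block mass steps, and only in
this fine-grained regime is it neutral with respect to intake (coarse,
bursty bouts would put genuine feeding deltas into the rejection tail,
censoring intake in exactly the high-expenditure hours). Behavior episodes
remain discrete (feeding/drinking visits, short off-sensor spells, and
whole nights asleep on the food dish with probability 0.25 — the source of
the ±27 g recode events). Refills are single positive steps (food +50 g
every 4 days, water +150 g every 5 days) sized above the 35 g recode bound,
as dish/bottle replacements produce. Load cells: Gaussian noise 0.03 g at
1 Hz (HX711-class), linear drift 0.5/0.04/0.05 g day⁻¹ (perch/food/water —
the empty-chamber values measured for this hardware), tares every 2.5 days.

**RFID.** Temperature-sensitive PIT-tag reads every 2 s gated on behavior
(perch within ~13 cm of the antenna); body temperature 41.5 °C lights-on /
40.0 °C lights-off plus slow noise. No body-temperature values are published
for this system's focal species in text form, so the Tb defaults are free
parameters.

**What the generator does not emulate.** Digestion/SDA dynamics, activity as
a metabolic state beyond the day/night factor, social effects, breakpoints
in thermoregulation (the piecewise-linear model has a single LCT), feather
or posture effects on conductance, RH–temperature covariance, analyzer span
nonlinearity, RTC clock drift between loggers, and SD-card corruption.
Passing tests therefore demonstrate that the pipeline is correct and
near-unbiased *under this generative model*, not that real data are free of
biases the generator omits.

## 5. Numerical and design choices

- All recurrences (washout, analyzer response, AR(1) noise) use
  `scipy.signal.lfilter` with exact exponential coefficients; fixed seeds
  (NumPy `SeedSequence` spawning per stream) give bit-identical runs.
- Stable-segment and min-SD block ties resolve to the earliest candidate;
  rolling SDs use the n−1 denominator.
- `integrate_rates` anchors bins at multiples of the bin width on the
  experiment clock; hours = clock hours, days = experiment-local midnights,
  consistent with the 12:12 light schedule anchoring.
- Metabolic point timestamps are stable-segment midpoints, so per-chamber
  spacing is 480 ± ≤15 s rather than exactly 480 s.
- Intake deltas are stamped with the later stable point's time; an intake
  step is credited to the bin in which it completed.
- "Hour" enters the models as a 24-level categorical factor (absorbs
  circadian shape without assuming linearity); bird ID is a categorical
  fixed effect; model selection fits all predictor subsets and picks minimum
  AIC, with ties to the smaller model. Rank-deficient designs raise instead
  of silently dropping terms.
- The reported degrees of freedom of the source analyses imply an hour
  encoding that cannot be uniquely reconstructed; exact df replication is
  not attempted.
- Validation campaigns are sized to run in seconds-to-minutes: the test
  suite uses 3-bird × 3-day and 1-bird × 2-day campaigns; the acceptance
  script pools four 3-bird × 10-day replicates (the full reference campaign
  length).

## 6. Known limitations

- **Filter censoring under coarse intake.** If real birds take large,
  infrequent meals (per-10-min steps comparable to 3 empirical SDs of the
  delta distribution), the 3-SD rule censors the intake tail and biases
  intake–EE slopes low. The pipeline inherits this from the protocol it
  reimplements; `ProcessingOptions.outlier_k` can be relaxed.
- **Transition artifacts.** Large, fast temperature steps (≫2 °C at once)
  drive ambient-humidity and washout transients whose τ-amplified derivative
  can produce outlier metabolic points near the step; the daily-minimum-MR
  order statistic is the most sensitive consumer. The reference protocol's
  gentle daily steps avoid the regime.
- **Uncorrected CO₂/H₂O lag.** Only O₂ receives the instantaneous
  correction (as in the acquisition macro), so V̇CO₂/V̇H₂O lag true rates by
  ~τ during transients; steady-state values are unaffected.
- **V̇H₂O approximation.** The dry-basis mixing-ratio conversion uses the
  excurrent dry flow for the incurrent water term, a ≲0.02 % error at
  reference flows.
- **Body-mass presence band.** Perch readings identify "bird on perch" by a
  15–45 g plausibility band; birds lighter than ~15 g or perch drift beyond
  the band would need the band reconfigured.
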