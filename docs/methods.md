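# Methods

## Model

One animal-day is described by two coupled sub-models.

**Animal.**  Instantaneous O2 consumption and CO2 production (L STP/h)
are sums of independent drivers:

* a constant resting level, VOFED / VCFED (L/h), on fed days;
* an activity term proportional to the force-transducer voltage u(t):
  VOFOR·u, VCFOR·u (L/(mV·h));
* a meal-locked thermic-effect term.  Feed intake (g, from the trough
  scale) fills the first of two compartments in series, each emptying
  at the fractional rate k = 2/TTEF (1/h):

      dC1/dt = r(t) − k C1,     dC2/dt = k (C1 − C2),

  and the gas response is O2TEF·k·C2 (resp. CO2TEF·k·C2).  The impulse
  response is the Erlang-2 kernel k²·t·e^(−kt): unit mass, peak at
  TTEF/2, mean transit time TTEF.  This kernel is kept as an analytic
  test oracle against the state-space implementation;
* optional manually annotated events, modeled as rectangular pulses of
  extra exchange.  Their daily contribution is expected below 0.5% of
  the total; they exist so that short artefacts do not bias the fit.

On the fasting day there is no feeding term and the resting level
declines first-order from the fed level to the fasting asymptote:
V(t) = VFAST + (VFED − VFAST)·e^(−t/τ), with separate time constants
TOADAP, TCADAP (hours) for the two gases.  The activity term stays
active; residual thermic-effect carry-over from the previous fed day is
not modeled separately — it is absorbed by the declining resting level.
The fast is taken to start at midnight of the fasting day.

**Chamber.**  The chamber air is O2 + CO2 + N2, tracked as STP
inventories (L at 0 °C, 1 atm).  Only the outflow is measured; the
inflow is defined as the flow that keeps the chamber's STP volume
constant given outflow and net exchange, Fin = Fout + VO2 − VCO2
(− VCH4 when methane bookkeeping is on), which is exactly the
"RQ effect" on the inflow–outflow difference.  Each concentration is
its inventory over the summed inventory.  Methane inventory dynamics
are deliberately not modeled; a constant CH4 production rate enters
the inflow balance and yields the quasi-steady outgoing fraction
VCH4/Fout, enough for daily energy bookkeeping.

### Integration

Because the inflow closes the volume balance, the total inventory is
constant and each gas obeys a *scalar linear* ODE with known
time-varying coefficients.  The default integrator therefore holds all
drivers constant over each 10-s tick and advances every state with the
exact exponential update (the TEF cascade likewise, through its
constant-coefficient recursion).  This is exact for the stated driver
model, unconditionally stable, and fast enough to sit inside a simplex
search.  A fixed-step classical RK4 integrator over the full coupled
system is retained (`method="rk4"`) as an independent numerical route;
the two agree to ~1e-15 in concentration on realistic days, and the
tests exercise both.  Refining the grid (10 s → 5 s) changes daily
volumes by far less than 0.1%.

## Preprocessing

* **Drift**: analyzers are calibrated at both ends of the day against
  ingoing air (baseline) and a standard gas (span); drift is linear in
  time, and each tick is mapped through the interpolated two-point
  (offset + gain) correction.  A missing end calibration requires the
  caller to enable carry-forward explicitly.
* **Lag**: analyzer traces are shifted 70 s earlier (the transport lag
  from chamber to analyzers); the trailing edge is filled with the last
  value and flagged, and fitting masks the filled ticks.
* **STP**: flows recorded at chamber conditions are converted with the
  ideal-gas law after removing water-vapor partial pressure (Tetens
  saturation formula × relative humidity).  The vapor correction is
  applied before the temperature/pressure rescaling and can be
  disabled.
* **Volumes**: per-tick VO2/VCO2/VCH4 by the inert-gas (Haldane-type)
  balance — inflow from the N2 balance, not assumed equal to outflow —
  with a chamber storage term V·dx/dt so transients close.  Ticks
  inside interruption windows are excised; daily volumes are scaled to
  24 h assuming proportionality.  The proportionality assumption is a
  real approximation: the excised morning window (feeder blocked since
  06:00, care at 08:00) does not carry average metabolism, which costs
  ~0.5–0.7% on daily volumes.  On uninterrupted noise-free days the
  round trip against the simulator is exact to ~0.01%.
* **Smoothing**: missing samples are linearly interpolated; drivers
  (force, temperature, pressure, outflow) get a 6-tick centered moving
  average (integral-preserving).  The exact method used originally is
  unknown; both the method and window are configurable.

## Fitting

Per-day weighted least squares on the measured gas fractions,
Nelder–Mead (reflection 1, expansion 2, contraction 0.5, shrink 0.5;
adaptive coefficients when more than five free parameters), budget
5000 evaluations per step, relative SSE tolerance 1e-8, one restart
from a perturbed best point on stagnation.  Three stages, following
the "separately, then together" estimation order: O2-related parameters
(VOFED, VOFOR, O2TEF, TTEF) on O2 residuals; CO2-related (VCFED,
VCFOR, CO2TEF) on CO2 residuals with TTEF carried over; joint
refinement of all seven on the equally weighted combined residuals.
All parameters are strictly positive and are searched in log space.

Starting values are data-driven: resting levels from the median
quiet-night tick rates (activity in the lowest quartile before 06:00),
activity coefficients from the regression of tick rate on voltage, and
the feeding coefficients from the daily exchange left unexplained by
the other two terms.  Generic literature-scale starts (0.2 L/g) proved
fragile — on some days the O2 stage collapsed the feeding term into the
resting level — while the data-driven start lands close enough that the
staged search converges to the generating optimum on every tested day.

The predicted day anchors its initial chamber composition at the first
observed tick, treats the measured daily CH4 rate as a known constant,
and masks interruption windows and lag-filled edges from the residual.
Days without feed (or without activity) leave the corresponding
coefficients structurally unidentifiable; they are frozen at zero and
flagged rather than estimated.

The fasting fit estimates VOFAST, VCFAST, TOADAP, TCADAP and the
activity coefficients, with the fed levels fixed at the mean of the
animal's fed-day fits (re-estimation is available).  Estimated
asymptotes above the fed level are clipped to it with a warning.

## Partition and balance

Heat production uses the Brouwer-type coefficients 16.18, 5.02, 2.17,
5.99 (kJ per L O2, L CO2, L CH4, g urinary N, ammonia included).  The
coefficients live in one place and are overridable.  Components: AHP
and TEF_s from the fitted per-component volumes (TEF_s credited to the
day of the meal, with the past-midnight kernel tail flagged above 1%);
FHP as 24 h at the fasting asymptotes minus the fasting-day urinary-N
term (fasting-day N is used, not a fed-day average); TEF_l as the
residual HP − AHP − TEF_s − FHP, clipped at zero with a warning when
negative (that signals fed/fasting inconsistency the user must see).
Additivity of the four components to measured HP is then exact by
construction.

Balance quantities follow the standard constants (PD = 6.25·N_ret;
RE retained as 23.6 kJ/g protein and 39.7 kJ/g fat; CH4 at 39.5 kJ/L;
metabolic size BW^0.60 using the mean of start and end BW).  Periods
pool six fed days; per-day values are the pooled totals divided by
days.

## Standardization

The cohort-mean AHP/ME ratio (mean of per-animal ratios, never the
ratio of means) fixes AHP_c = ratio·ME for every animal; the energy
moved by the correction is split between TEF and RE via
ΔTEF = (AHP − AHP_c)·TEF/(ME − FHP − AHP), identically on both
branches (AHP above or below AHP_c).  FHP + AHP_c + TEF_c + RE_c = ME
is conserved exactly; protein deposition is held fixed so only fat
deposition absorbs the RE adjustment.  The ratio is always computed
from the cohort; a configuration override reproduces any externally
fixed value (e.g. the published 8.6%).  A missing FHP is imputed as
the mean FHP of same-class animals on the metabolic-size scale, and
flagged.  Group summaries are arithmetic means; published tables are
least-squares means from a two-factor linear model, so ±1–2 units of
discrepancy against printed LS-means are expected and not chased.

## Synthetic cohorts

The generator mirrors the design of the reference experiment: six
groups × three sex classes, ~115 kg pigs, six fed days and one fasting
day each, in a 12 m³ chamber ventilated at ~7500 L STP/h.  Class-level
magnitudes are calibrated to the published LS-means (ME 2400–2900 and
FHP 730–860 kJ/kg BW^0.60/day, total TEF 13–17.5% of ME, resting fed
RQ 1.08–1.15, PD 196–261 g/day) with between-animal SDs of realistic
size; the AHP/ME ratio is drawn around 8.6% (SD 1.5 points).  Feeding
is a marked point process (uniform bout times outside the 06:00–09:00
feeder lockout, lognormal sizes rescaled to the day's intake, constant
eating rate); activity is rectangular bouts with lognormal amplitudes
drawn independently of duration over a low baseline — which reproduces
the observed decoupling of standing time from activity heat.  The
instrument layer applies linear analyzer drift (with matching
calibration records), the 70-s lag, Gaussian analyzer noise (SD 0.002
%-points), force and outflow noise, measured-condition flow recording,
and a 15-min blanked interruption at 08:00.  Everything derives
deterministically from the scenario seed via per-day child seeds.

What the generator does *not* emulate: model misspecification.  Real
animals violate the constant-resting-level and fixed-cost-per-mV
assumptions, which is why published fits report R² ≈ 0.92 while fits
to synthetic days reach R² ≈ 0.999.  Passing recovery tests therefore
demonstrate the correctness of the estimation machinery, not the
adequacy of the day model for real pigs.  Slow physiological drifts,
circadian hormone effects, posture-dependent muscle efficiency and
multi-animal chambers are all out of scope.

## Numerical choices and edge cases

* Inventories driven non-positive raise a simulation error naming the
  failure time instead of returning garbage.
* The Haldane computation refuses days whose computed VO2 stays
  negative over a sustained (10-min) window.
* 24-h standardization rejects durations above 24 h; corrections
  reject ME ≤ FHP + AHP, naming the animal-day.
* Sizes used in the shipped tests and the acceptance script — 20 noisy
  fed days for recovery, 8 in the script, 6-animal end-to-end cohorts,
  1000-record conservation sweeps — were chosen to keep the full
  default run around a minute while leaving the Monte-Carlo margins
  comfortable.
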