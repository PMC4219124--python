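# Methods

## Model

`cardiorc` models heart-rate (HR) and oxygen-uptake (VO₂) responses to
piecewise-constant treadmill workloads with a single-supply switching RC
circuit.  The output is the voltage of capacitor *C₁* above the warm-up
baseline (taken as zero); units of *V* and of all voltages are the
physiological units of the configured signal (Δbpm or Δml·min⁻¹), and all
R·C products are times in seconds.

Three operating modes, selected by the protocol:

**Onset** (workload step up).  The diode shorts *R₂* and the supply
charges *C₁* through *R₁*:

    dv₁/dt = (V − v₁)/(R₁C₁)        ⇒  v₁(t) = V + (v₁(0) − V)·e^(−t/R₁C₁)

so the onset time constant is `T_on = R₁C₁` and the asymptote is *V*.
*C₂* is disconnected and holds its charge (see "Open choices" below).

**Offset** (workload step down).  *C₁* discharges through the series loop
*R₁ + R₂* into *C₂*; the current through the much larger *R₃* is
neglected.  With loop current `i = (v₁ − v₂)/(R₁+R₂)`:

    C₁ dv₁/dt = −i,    C₂ dv₂/dt = +i.

Charge `C₁v₁ + C₂v₂` is conserved; both voltages relax exponentially with
`T_off = (R₁+R₂)·C₁C₂/(C₁+C₂)` toward the common equilibrium
`v_eq = (C₁v₁ + C₂v₂)/(C₁+C₂)`.  The offset loop resistance includes
*R₁*: with the published component values, `(R₁+R₂)·C₁C₂/(C₁+C₂)` tracks
the measured offset time constants with the same small tuning offset as
`R₁C₁` does the onset ones, whereas an *R₂*-only loop would be off by a
factor of two.

**Recovery** (long-term return to baseline).  The same loop with *R₃*
shunting *C₂*:

    C₁ dv₁/dt = −i,    C₂ dv₂/dt = i − v₂/R₃,

a genuine two-state linear system whose eigenvalues are real and negative
(the state matrix is similar to a symmetric one).  Both capacitors drain
to zero; with the default `R₃ = 100·(R₁+R₂)` the slow drain mode has time
constant ≈ `R₃(C₁+C₂)`, i.e. recovery to baseline is deliberately much
slower than the charge-sharing phase, as the large-*R₃* idealization
implies.

### Coefficient mapping

Normalizing gains by the workload step Δu (km/h):

    K_on  = V/Δu,                 T_on  = R₁C₁,
    K_off = K_on·C₂/(C₁+C₂),      T_off = (R₁+R₂)·C₁C₂/(C₁+C₂).

Given measured (K_on, T_on, K_off, T_off) and a free, pre-chosen *R₂*
(default 100 Ω), with `g = K_off/K_on`:

    C₁ = (T_off/g − T_on)/R₂,   R₁ = T_on/C₁,
    C₂ = C₁·g/(1−g),            V = K_on·Δu,   R₃ = 100·(R₁+R₂).

This is the exact inverse of the forward map; infeasible inputs
(`K_off ≥ K_on`, or `T_off/g ≤ T_on`) raise an error naming the violated
constraint.  Feasibility has physiological content: the circuit can only
realize the empirically observed regime `K_off < K_on` with
`T_off` not too small relative to `T_on`.

### Scheduling and numerical stepping

Protocol segments map to modes (warm-up idles at baseline, onset → onset,
offset/cool-down → offset); the run hands over to recovery at the later
of the cool-down start and the instant `|v₁ − v₂| < 10⁻³·V` (this instant
is *t₂*, computed analytically from the offset decay).  All stepping is
exact piecewise-exponential (eigen-decomposition for the recovery pair),
sampled on a uniform grid (default 1 s, segment boundaries use half-open
`[start, end)` intervals); the capacitor state is carried bit-exactly
across every switch, so output continuity at switches is a construction
property, not a numerical achievement.  A generic adaptive ODE
integration of the node equations (`scipy.integrate.solve_ivp`, DOP853,
rtol 1e−12) is kept in the test suite as an independent oracle; agreement
is ≤1e−8 absolute on windows of a few time constants (longer recovery
windows are capped in the comparison because the *integrator's*
accumulated error, not the closed form, grows past that floor).

## Identification

First-order fits use bounded nonlinear least squares
(`scipy.optimize.least_squares`), *T* bounded to (1, 600) s, initial
guesses `K₀ = (final − baseline)/Δu` and `T₀` = time to 63.2% of the
excursion.  Onset windows are fitted baseline-anchored with the baseline
taken as the value at the window start; offset windows are fitted as
free-asymptote decays `y = c + A·e^(−t/T)` with `K_off = |A|/Δu`, so the
reported offset gain is a positive magnitude and no assumption is made
that recovery returns to the pre-exercise baseline.  Degenerate inputs
(zero step, flat signal, <10 post-step samples) raise errors rather than
returning garbage.

The noise-free round trip (simulate → fit) recovers generating parameters
to better than 1e−6 relative.  The full table round trip — configure a
circuit from the population coefficient means (R₂ = 100 Ω, Δu = 4 km/h),
simulate, re-fit — recovers all eight HR/VO₂ coefficients to ≤1e−3
relative.  For that round trip the package uses a square wave with a
900 s onset and 420 s offset rather than the 360 s/300 s experimental
bout: a 360 s onset leaves a residual `e^(−360/60.6) ≈ 2.6·10⁻³` of the
plateau unreached, which propagates into the offset amplitude and would
contaminate the recovered K_off at the same order.  The choice is an
identification-experiment design decision (settling-length windows on
noise-free data); the experimental-length protocols remain the defaults
everywhere else.  The offset window is kept shorter than the equilibrium
time so the fitted slice is the pure charge-sharing decay.

## Energy areas

Over one onset/offset cycle, trapezoidal quadrature on the simulation
grid gives (units: response-unit·seconds):
credits = ∫v₁ over the onset bout; deficit = V·(bout length) − credits;
offset_total = ∫(v₁ − v₁(t₂)) over [t₁, t₂]; debt = min(deficit,
offset_total) — "the debt repays the deficit" is adopted as a definition;
storage_extra = offset_total − debt; and the corresponding *C₂*
accumulation area.  *t₂* is the last grid sample of the charge-sharing
window (the next sample already leaks through *R₃*, which would break the
1e−6 charge-conservation contract of the storage balance).  Offset areas
are referenced to `v₁(t₂)` by default; a baseline-referenced variant is
available via `reference="baseline"`.  The stroke-volume scale SV
defaults to 1, so areas are reported in response units; cardiac-output
scaling (Q = SV·HR) is left to the caller.  `deficit + credits` tiles the
`V × duration` rectangle exactly (trapezoid is exact for the constant);
the pure-onset closed form `deficit → V·T_on` is met to ~1e−5 relative at
1 s sampling, consistent with the O(dt²/12T²) trapezoid error.

## Synthetic cohorts

The generator emulates a study in which each subject's kinetics are
first-order with subject-specific coefficients, every exercise is
repeated twice, and traces are filtered, interpolated to 1 Hz, and
averaged.  Defaults: 20 subjects × 2 trials, coefficient distributions
equal to the published HR/VO₂ population means and STDs, additive i.i.d.
Gaussian measurement noise of 2 bpm (HR) and 60 ml·min⁻¹ (VO₂) — chosen
as plausible beat-to-beat/breath-by-breath scatter, since the study
design specifies none — and a 5-sample centered moving average applied
after trial averaging.  Per-subject traces are piecewise first-order
composites: at each speed change the response re-targets from its current
value (upward step → onset coefficients, downward → offset), so traces
are continuous at switches by construction.

Coefficients are drawn independently per coefficient (no within-subject
covariance is modelled; none is published), truncated to positive, and
the quadruple is resampled until `T_off > T_on` and `K_off < K_on` — the
empirically observed regime.  This joint truncation shifts the realized
T_on mean a few seconds below the nominal population mean (verified
against an independent vectorized accept-reject draw); recovery tests
therefore compare fitted coefficients with the coefficients actually
generated, which is the estimator-bias question the pipeline can answer.
What passing these tests shows is that the identification pipeline is
consistent on data generated by its own model class with stationary
Gaussian noise; it does not establish robustness to real-data features
such as breath-by-breath artifacts, drift, cadence-locked oscillations,
or violations of first-order kinetics.

All randomness flows from a single seed through one
`numpy.random.Generator`; identical specs produce bit-identical cohorts.

## Open choices and limitations

* *C₂ during a subsequent onset* (interval training): held by default
  (the onset subcircuit gives it no path); a bleed-through-*R₃*
  alternative is available (`c2_onset="bleed"`).
* *Equation forms*: the diode is ideal (zero drop/leakage); no SPICE-level
  effects.  The dual-supply threshold-based switching circuit from the
  earlier literature is out of scope.
* *Tuned vs derived components*: published "tuned" component tables need
  not equal the closed-form configuration from the population means; the
  package never forces that equality (e.g. `V = 55.11` vs
  `K_on·Δu = 53.4` for HR).
* *R₃ invariant*: constructors default to `R₃ = 100·(R₁+R₂)`; manually
  supplied smaller values warn (the ideal-offset approximation degrades)
  but are allowed for exploring the non-ideal regime.
* Problem sizes in the test and acceptance runs (1000 inversion sets, 100
  oracle circuits, 200-subject cohorts, 25-sample ODE grids) are chosen
  so the statistical bounds they check are comfortably resolved while the
  whole suite stays interactive-fast.
* The verification metrics (RMSE, Pearson correlation reported as a
  percentage) compare any two aligned traces, but published fit
  statistics against the original treadmill measurements cannot be
  reproduced here: those recordings were never deposited.
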