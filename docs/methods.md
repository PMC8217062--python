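# Methods

## Governing model and assumptions

The package models the fluid in a vessel (renal collecting system, calyx,
or benchtop cell) as one well-mixed thermal compartment. The energy balance

    ρ c V dT/dt = W(t) + ρ c Q (T_in − T) − β (T − T_0)

combines three linear terms: laser power deposited into the fluid while
firing, advective exchange with irrigation (inflow at T_in, outflow at the
compartment temperature — perfect mixing), and Newton cooling through the
wall to a bath at T_0 with conductance β = h·s. Assumptions worth keeping in
mind:

* **Single temperature.** No spatial gradients are resolved; the prediction
  is a volume average and a *lower bound* on local hot spots near the fibre
  tip. Spatially resolved predictions need a full CFD/FE treatment.
* **Constant properties.** ρ and c are fixed (water values); buoyancy and
  temperature-dependent viscosity are ignored. Thermal conductivity `k` is
  carried in `FluidProperties` for completeness but does not enter the
  lumped solution.
* **Linear wall loss.** β lumps the wall heat-transfer coefficient and area
  into one fitted constant per vessel; it is the only parameter that cannot
  be set from first principles.
* **All laser power becomes heat in the fluid.** Energy spent fragmenting
  stone is neglected (conservative for safety).

Because every term is linear, each constant-power phase has the closed form
`T(t) = T* + (T_start − T*) exp(−Δt/τ)` with
`T* = (W + ρcQ·T_in + β·T_0)/(ρcQ + β)` and `τ = ρcV/(ρcQ + β)`. Two
structural consequences are load-bearing throughout the package and are
property-tested: the steady state is independent of V, and τ scales
linearly with V (a small calyx equilibrates in seconds, a full collecting
system in minutes — which is why small working spaces are the dangerous
ones). Schedules with arbitrary on/off intervals are propagated phase by
phase with exact continuity at every switch; at a switch instant the
left-phase endpoint is used (continuity makes the choice unobservable).

With `Q = 0` and `β = 0` there is no heat sink: `heat_load` raises
(`UnboundedHeatingError`, no steady state exists) while `temperature_at`
returns the exact linear ramp `W·t/(ρcV)`.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| V | vessel volume | m³ (mL at interfaces) | preset: 5.89 / 38.3 mL |
| Q | irrigation rate | m³/s (mL/min at interfaces) | 0 |
| T_in | irrigation temperature | °C | bath temperature |
| T_0 | bath / initial temperature | °C | preset: 37 / 22 |
| W | laser power | W | — |
| β | wall conductance h·s | W/°C | preset: 1.15 / 1.36 |
| ρ, c, k | fluid properties | SI | water: 1000, 4180, 0.606 |

Interfaces (CLI flags, config files, scan tables) use clinical units — mL,
mL/min, °C, W — and convert to SI exactly once on ingestion. Temperatures
stay in °C throughout; the model is offset-invariant so no Kelvin
conversion is needed.

## Thermal dose

`t43 = ∫ R^(43 − T) dt` (reported in minutes) with R = 0 at or below 37 °C,
0.25 strictly between 37 and 43 °C, and 0.5 at or above 43 °C; the branch
points are inclusive exactly as written. The integrand is evaluated by
adaptive quadrature (relative tolerance 1e-8) separately on each analytic
phase, with the 37 °C and 43 °C crossing times — available in closed form
per phase — passed as breakpoints so the R-discontinuity at 37 °C and the
kink at 43 °C never degrade convergence. Sampled traces use the composite
trapezoid rule on the integrand at the samples.

**Integration horizon.** Dose is integrated from laser-on through the
cool-down. When the off-phase asymptote is below 37 °C the integral ends
exactly at the (closed-form) downward 37 °C crossing and is complete. When
the asymptote is at or above 37 °C the tail integrand never vanishes
(`0.25^(43−37) ≈ 2.4e-4` min/min even in the limit) and the integral
diverges; the horizon is then cut 10 time constants into the trailing phase
(600 s when no time constant exists) and the result carries
`truncated=True`, marking it a lower bound. The tail length is configurable
(`tail_taus`). This matters precisely for body-temperature irrigation
(T_in = T_0 = 37 °C), where any heating accrues dose indefinitely.

## Safe firing time

`safe_firing_time` returns the largest single-burst firing time whose dose
(firing plus cool-down, policy above) stays at or below the threshold
(120 min by default). The on-phase steady state T* splits three regimes:

* `no-dose` (T* ≤ 37 °C): the curve never exceeds 37 °C, dose is
  identically zero, the safe time is infinite. This is decided in closed
  form, not numerically.
* `sub-43` (37 < T* < 43 °C): dose accrues at < 1 min/min; the safe time is
  finite but can be enormous.
* `supra-43` (T* ≥ 43 °C): dose accrues at ≥ 1 min/min near the plateau;
  safe times are minutes.

Because `t_f ↦ t43(t_f)` is non-decreasing (property-tested), the solver
brackets the threshold crossing by geometric growth from 60 s and bisects to
1 ms. If the bracket exceeds 24 h of continuous firing the safe time is
reported as infinite with an explanatory note — relevant in the `sub-43`
regime where the accrual rate can be ~2e-4 min/min. Truncated dose
evaluations encountered during the solve are propagated as a
`dose_truncated` flag rather than silently ignored. Re-evaluating the dose
at the returned time reproduces the threshold to < 0.1 min (asserted in
tests and recomputed by the acceptance script).

The scan helpers tabulate ΔT after a fixed firing time over two of
(Q, W, V), and safe time over (T_in, Q); the latter also reports, per
irrigation temperature, the closed-form flows at which T* crosses 37 and
43 °C, which depend only on (W, β, T_in, T_0) — never on V.

## Fitting the wall conductance

β is identified from the still-fluid (Q = 0), 40 W protocol, where the rise
curve `T_0 + (W/β)(1 − e^(−βt/ρcV))` depends on β alone. The fit minimises
the unweighted sum of squared residuals between the analytic curve and all
pooled trace samples in the fit window — laser-on to laser-off by default,
matching the identification protocol; the window is configurable.
Homoscedastic noise is assumed (thermocouple noise has no reported
structure), which makes pooling repeated runs equivalent to fitting their
pointwise mean on aligned grids (tested). Minimisation is bounded scalar
search on [1e-3, 1e2] W/°C with tolerance 1e-6, preceded by a 25-point
log-spaced scan that (a) rejects non-identifiable data (flat objective —
e.g. no firing or no gradient) and (b) warns if the objective is not
unimodal. The standard error is curvature-based:
`var(β̂) = 2 σ̂² / (d²RSS/dβ²)` with σ̂² = RSS/(n−1) and a central-difference
second derivative. Estimates at a search bound raise a warning and are
flagged in the result.

## Synthetic data

`synthetic.generate_grid` emulates the benchtop acquisition grid: two
powers (10, 40 W) × three flows (0, 20, 40 mL/min) × five runs, each 0–100 s
at 0.1 s (20 s irrigation-only lead-in, 60 s firing, 20 s cool-down), for
either preset. Traces are the analytic solution plus i.i.d. Gaussian noise,
σ = 0.2 °C by default — an assumed, plausible T-type thermocouple precision;
no empirical noise model exists. Sub-seeds are spawned per (cell, run) from
the root seed, so any run regenerates independently and bit-identically.

What passing tests on this data do **not** show: robustness to flow-rate
drift within a run, probe-placement effects, wall-property variation, or
any model misspecification — the generator and the fitted model share the
same functional form by construction. Parameter-recovery results are
therefore statements about noise, not about model adequacy. (Optional
flow jitter was considered and left out; it would only speculate about
unreported run-to-run variability.)

## Numerical choices

* **Verification oracle.** A fixed-step classical RK4 integration of the
  balance ODE, phase-aligned (a shortened final step lands each switch
  exactly). For this scalar linear ODE the RK4 update is an affine map, so
  the stepping is evaluated as a closed recurrence — identical results to a
  step loop, at vector speed. It converges at 4th order (tested) and agrees
  with the analytic solution to < 1e-2 °C at dt = 1 ms across randomized
  configurations and duty cycles; it is used only in tests.
* **Tie-breaks and degenerate input.** Left-phase value at switch times;
  linear-ramp branch when Q = β = 0; empty schedules are pure relaxation
  to the irrigation/bath equilibrium.
* **Statistical bound in the noise-averaging test.** The mean of 500 runs
  deviates from the model with per-point SE σ/√500 ≈ 0.009 °C; the maximum
  over 1001 samples concentrates near √(2 ln 1001) ≈ 3.7 SE ≈ 0.033 °C, so
  the test asserts RMS < 1.35·SE and max < 5·SE rather than a bound below
  the expected extremum.
* **Problem sizes.** Tests use 100-config oracle sweeps at 0.5 s output
  resolution over 200 s, 200-repetition Monte-Carlo recovery with 5 runs
  each, and small (≤ 7×7) scan grids — large enough to exercise every
  regime, small enough to keep the suite in seconds.

## Known limitations

* Volume-averaged only: local temperatures at the fibre tip will exceed the
  prediction; safety margins should account for that.
* β must be fitted per vessel/tissue; the shipped presets are benchtop
  values, not in vivo ones.
* The dose integral for body-temperature irrigation is horizon-limited by
  construction (see above); compare only like-for-like truncation policies.
* The rise-time ∝ volume relationship is a model statement about the lumped
  time constant; anatomies with poor internal mixing violate the
  well-mixed premise that underlies it.
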