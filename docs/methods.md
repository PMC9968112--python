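# Methods

`pfasim` simulates the electro-thermal(-fluid) physics of cardiac pulsed
field ablation (PFA) on a synthetic tissue–blood–catheter geometry and
compares two treatments of blood cooling: fixed convective-coefficient
Robin boundaries (**CHT**) and a resolved laminar blood flow (**CFD**).
This note records the model, the numerical choices, and what the
synthetic setting can and cannot say about the full-anatomy problem.

## Geometry

The left atrium is reduced to a planar 2-D longitudinal section through
the catheter axis: a myocardial slab of wall thickness 2.4 mm (the mean
human LA wall) at the bottom, a blood channel above it (default height
8 mm), and a straight two-electrode catheter lying parallel to the
epicardium, pressed 1 mm into the endocardium. The catheter is 7 F
(2.333 mm) in diameter with a bare 2 mm tip electrode, a 2.5 mm
insulated gap, a second 2 mm electrode and a 2 mm insulated proximal
shaft. The bottom of the slab is the epicardium (zero electric and
thermal flux); the channel's short ends are the flow inlet and outlet.

"Volumes" reported from the planar mesh are areas times an extrusion
depth (default: the catheter diameter), a convention carried through
all outputs. An extruded 3-D slab variant exists for geometry and I/O
work; the solver stack operates on the planar section.

The mesh is a tensor-product grid of rectangles with local refinement:
cells within the catheter footprint (plus a 2 mm margin) honour a
0.4–1.0 mm element band (the resolution at which full-anatomy ablation
models report mesh convergence); grid lines are snapped to every
material boundary so region areas are exact.
The default reference fixture has 774 cells; the parameter-sweep
observables were cross-checked on a 2.1k-cell refinement (0.25–0.7 mm
band) with materially identical comparison statistics. The small
default keeps a full two-method parameter sweep within minutes on one
CPU; this is the package's problem-size choice for the desk-scale
study.

## Electrical model

The potential obeys `div(sigma grad V) = 0` with the pulse amplitude on
the tip electrode, ground on the second electrode, and zero flux on the
shaft and epicardium. Myocardial conductivity is both field- and
temperature-dependent:

* a sigmoid in |E| between the pre- (0.0537 S/m) and post-
  electroporation (0.281 S/m) values, centred at 58 kV/m with 3 kV/m
  width;
* exponential growth of 1.5 %/°C above 37 °C up to 100 °C, then a
  linear desiccation ramp `1.371 − 0.274 (T − 100)` to 105 °C and a
  desiccated floor of 1.371×10⁻⁴ S/m.

The printed desiccation intercept (1.371 S/m) does not join the growth
branch continuously (the growth branch reaches ≈0.72 S/m at 100 °C with
saturated sigma); the law is implemented exactly as printed, with an
optional `continuity_mode` that rescales the ramp to start at the
growth-branch value. Below 37 °C the 37 °C value is used — with a
37 °C ambient and nonnegative sources the simulation never goes there.

Discretisation: vertex-centred finite volumes (box scheme) on the
tensor grid — nodal potential, piecewise-constant per-cell conductivity
and field. On a uniform grid with uniform conductivity the scheme
reduces exactly to the classical 5-point stencil, which is how the test
suite cross-checks it against an independent dense solve. Electrode
cells are Dirichlet sets (the metal is 4.6×10⁶ S/m, effectively
equipotential; the field inside is exactly zero so the metal receives
no spurious Joule heat).

The sigma(E) fixed point (solve → field → update sigma → re-solve) is
accelerated with Aitken (Irons–Tuck) dynamic relaxation on the sigma
residual, clipped to [0.05, 1]. The electroporation sigmoid is steep
enough that plain or fixed-factor under-relaxed iteration limit-cycles
around the threshold cells; Aitken converges in ~20 iterations at a
1e-6 relative field tolerance. Within a 100 µs pulse the field is
re-solved (warm-started) whenever the myocardial conductivity drifts
by more than `sigma_resolve_rel` (default 1 %) from the last solve.

## Thermal model

Pennes bioheat without perfusion and metabolic terms (both negligible
on PFA time scales): `rho c dT/dt = div(k grad T) + Q − Qb`. The Joule
source `Q = sigma |E|²` acts during pulses only. Myocardial thermal
conductivity grows 0.12 %/°C from 0.531 W/m/K (37 °C) and plateaus at
0.606 above 100 °C. Water vaporization enters through the enthalpy
method: the effective volumetric heat capacity is `rho_l c_l` up to
99 °C, `Hfg·C` (2.162×10⁹ J/m³ × 0.75 per kelvin) on the 99–100 °C
band, and `rho_g c_g` above. Blood and catheter materials are constant;
blood is assumed not to undergo phase change.

Time stepping is backward Euler on a two-scale grid: ≤10 µs steps
inside each 100 µs pulse, ≤10 ms steps across the 250–1000 ms
intervals. The nonlinear capacity is handled with chord (secant)
slopes of the exact enthalpy curve inside a Picard loop, and each
iterate is projected back through the exact inverse enthalpy
(source-based enthalpy method): the energy the linear step deposits in
a cell is converted to temperature exactly, which keeps the iteration
stable across the three-orders-of-magnitude capacity jump at the band
edges and makes the phase plateau traverse with the correct energy at
any step size (verified to 0.4 % against the closed form).

Boundary treatment by mode:

* **CHT** — the blood region remains a solved, conduction-only medium.
  Robin conditions `n·k grad T = h (T − 37 °C)` replace conduction
  across the blood–myocardium (h_m) and blood–catheter (h_c) faces on
  both sides; they are the sole interface condition (the two regions
  are conductively decoupled there). h_m comes from inverting the
  reference power law `u = (h/h_ref)^1.25 u_ref` (h_ref = 1417 W/m²/K
  at u_ref = 24 cm/s), giving 984 W/m²/K at the 15.22 cm/s cycle-mean
  speed; h_c from the cross-flow correlation Nu = 0.683 Re^0.466
  Pr^0.333 with blood constants and the 7 F diameter, giving
  4372 W/m²/K. Both are computed once from the cycle mean and held
  constant. An alternate literature set (610/3346, from an 8.5 cm/s
  mean) is available as the `ref5` preset.
* **CFD** — ordinary conduction everywhere plus implicit first-order
  upwind advection `rho c u·grad T` in the blood, with 37 °C inflow.
  Advection is assembled into the backward-Euler matrix, so the 10 ms
  interval steps are unconditionally stable.

The discrete energy balance (stored enthalpy change = source − boundary
loss) closes to machine precision per run and is asserted to 1 % in the
tests.

## Blood flow

Laminar incompressible Navier–Stokes (µ = 2.1×10⁻³ kg/m/s; peak
Reynolds numbers ≈ 170 at the catheter, far below 2000) on the blood
cells with no-slip at the tissue and catheter interfaces. The solver is
a Chorin projection on a MAC staggered layout: explicit upwind
advection and central diffusion in the predictor, then a pressure
Poisson solve (factorised once per geometry) and a face-velocity
correction. Walls use quadratic no-slip ghosts, so a developed channel
profile is represented exactly; the plane-Poiseuille centreline test
passes within 1 %. Divergence after projection is at solver precision.

The inlet is a plug profile driven by a synthetic biphasic E/A-wave
waveform: two periodic von-Mises-shaped bumps (broad early-diastolic
E-wave, narrow late A-wave, default E/A peak ratio 1.5) rescaled to a
configurable cycle mean, default 15.22 cm/s over a 0.8 s cycle — the
quantity from which the CHT coefficients are derived. Because the
channel is wider than the catheter constriction, the inlet is scaled so
the cycle-mean speed *at the catheter* matches the configured mean. A
pressure-driven inlet (10 mmHg) is available as an alternative. The
outlet is a zero-pressure boundary.

Under rigid walls and temperature-independent viscosity the flow is
independent of the electro-thermal state, so one cardiac cycle is
precomputed (after one spin-up cycle, stored every 5 ms) and replayed
periodically for the whole pulse train; the velocity field is frozen
during each 100 µs pulse. The flow step size is set from the waveform
peak with a factor-2 margin on the advective CFL limit.

## Lesion criteria

* **IRE**: cells whose field magnitude ever exceeds 1000 V/cm
  (1e5 V/m) during the train, restricted to myocardium. The running
  maximum over pulses is used rather than the final pulse only, since
  sigma(T) drift can shift the field slightly between pulses; at
  matched settings the two coincide within tolerance.
* **50 °C isosurface**: cells at or above 50 °C at the end of the last
  pulse.
* **Arrhenius**: `Omega(t) = ∫ A exp(−ΔE/(R T_K)) dτ` with
  A = 2.94×10³⁹ s⁻¹, ΔE = 2.596×10⁵ J/mol, accumulated by rectangle
  rule on the solver grid over the whole trace (pulses *and*
  intervals — the natural reading of the integral); cells with
  Omega ≥ 1 (63 % damage probability) at the end of the last pulse.

Volumes are cell-indicator sums (no sub-cell interpolation), reported
in mm³ with the planar extrusion convention. A containment check
verifies that the hyperthermia sets are wrapped by the IRE set within
the myocardium.

## Comparison statistics

For each swept parameter (amplitude 1000/1500/2000 V, interval
250/500/1000 ms, count 10/30/60) both methods run on the same mesh and
the maximum myocardial and blood temperatures are sampled at the end of
the last pulse and the end of the last pulse interval. Differences are
reported signed (CHT − CFD) and as magnitudes; Pearson correlations
against the swept parameter use the magnitudes (the usual convention
for such differences, which are positive wherever CHT underestimates).
Significance flags follow the
measurement-driven thresholds: 1 °C for temperatures, 1 mm³ for
volumes. The pulse-number results pair counts 10/30/60 with a 250 ms
interval even though the protocol table lists 1000 ms for those groups;
both are supported and the sweep driver makes the choice explicit.

## What the desk-scale fixture shows — and does not

On this fixture the CHT method underestimates the CFD myocardial and
hyperthermia-volume results at every matched setting, IRE volumes are
method-independent, hyperthermia stays wrapped by IRE, and the
between-method difference grows strongly with pulse amplitude
(r ≈ 0.98) and pulse count (r ≈ 0.97).

The interval dependence is the known limitation. In the full-anatomy
problem the myocardial maximum sits on the contact line between
electrode and endocardium, wrapped transversely by flowing blood, so
the between-method difference tracks the interface cooling directly
and falls monotonically with longer intervals. A longitudinal 2-D
section cannot represent the transverse direction: its myocardial
maximum lies ~1.2 mm deep under the catheter body, shielded from the
blood, and interface-cooling differences reach it only by conduction
(τ ≈ d²/α ≈ 10 s). Across 250/500/1000 ms intervals the end-of-train
myocardial difference is then the product of a decreasing interface
signal and an increasing propagation factor — non-monotone, with a
correlation near zero instead of strongly negative. The mechanism is
still visible where the observable touches the interface: the *blood*
maximum difference falls monotonically with interval (r ≈ −0.9). This
was verified to be insensitive to mesh refinement (774 vs 2.1k cells),
to pulsatile-vs-steady flow replay, and to the field re-solve cadence.

The absolute full-anatomy temperature differences (tens of °C) are
likewise not reproducible at desk scale; this package reproduces the
signs, orderings and correlation structure, not those magnitudes.

## Defaults that matter

| parameter | default | units | origin |
|---|---|---|---|
| wall thickness | 2.4e-3 | m | mean human LA wall |
| catheter diameter | 7 F = 2.333e-3 | m | device |
| electrode / gap / insertion | 2 / 2.5 / 1 | mm | device & placement |
| element band near catheter | 0.4–1.0 | mm | mesh-sensitivity result |
| pulse width | 100e-6 | s | protocol standard |
| fine / coarse time step | 10e-6 / 10e-3 | s | resolves pulse heating and interval cooling |
| cycle mean speed | 0.1522 | m/s | ablation-site cycle mean |
| cardiac cycle | 0.8 | s | 75 bpm |
| h_m / h_c | 984 / 4372 | W/m²/K | derived from the mean speed |
| IRE threshold | 1e5 | V/m | cardiac IRE threshold |
| initial / ambient temperature | 37 | °C | body temperature |

## Known limitations

Rigid walls (no atrial contraction); single inlet/outlet channel in
place of the four-pulmonary-vein/mitral topology; 2-D section (see
above); flat-top monophasic pulses without the ~100 kHz internal
carrier; no electrode–tissue contact impedance; no irrigation; blood
phase change not modelled; cell-indicator lesion volumes without
sub-cell interpolation.
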