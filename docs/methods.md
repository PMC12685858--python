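# Methods

## Model

`emboflow` treats an arterial tree as a lumped (0D) hydraulic network.
Each vessel segment is a rigid cylinder with Poiseuille resistance
`R = 8μL/(πr⁴)`; junctions are lossless (pressure continuity, Kirchhoff
mass balance); the inlet is a volumetric flow source and every outlet a
Dirichlet pressure. For steady laminar incompressible flow of a Newtonian
fluid in such a network this is not an approximation scheme but the exact
solution of the governing equations restricted to unidirectional
fully-developed flow per segment. The nodal conductance system is sparse,
symmetric positive definite, and solved directly.

The deliberate reduction relative to 3D CFD: no secondary flows, no
recirculation eddies, no wall shear stress fields, no minor losses at
bifurcations (second-order at the Reynolds numbers of interest, ≈ 400),
no vessel compliance or fluid–structure interaction, no non-Newtonian
rheology. Every quantity the EEI analysis rests on — flow splits, junction
pressures, Reynolds numbers, retrograde segment flows — lives on the
network and is preserved. Spatial backflow patterns are reproduced only as
signed (retrograde) segment flows.

Pulsatile inflow is handled quasi-steadily: one steady solve per waveform
sample. Inertance and compliance (Womersley effects) are neglected; for
flow-*ratio* quantities such as the EEI this is consistent with the
linear, memoryless network. Waveform samples are left-endpoint uniform
over whole periods so that period averages of the sinusoidal harmonics
vanish exactly and time-averaged flows coincide with the steady solution
at the mean inlet flow (uniform outlet pressures).

## Embolization efficiency index

`EEI(s) = 100 × Σ(forward flow into target outlets downstream of s) / Q(s)`,
the perfect-mixing advective transport assumption: an embolic agent splits
at a bifurcation in proportion to the flow split, with no particle
inertia, size or density effects. Two conventions matter near stall:

- Retrograde target-outlet flows are clamped to zero in the numerator —
  an agent cannot be delivered by reverse outflow. Raw signed flows remain
  available on the `FlowSolution`.
- Sites whose carrier flow `Q(s)` is below 1e-12 m³/s report *undefined*
  rather than 0, so maps near flow cessation are not polluted by
  ill-conditioned ratios.

Structural consequences, all tested:

- With uniform outlet pressures the flow split is independent of the inlet
  flow magnitude (linearity), so the EEI map is exactly invariant under
  inlet rescaling — steady or pulsatile.
- EEI is non-decreasing along the inlet→target path; it is identically
  100 % at and below the target branch (all downstream leaves are
  targets).
- While every target outlet flows forward, superposition makes EEI at the
  inlet an exact affine function of the target total pressure (fit
  residuals at solver tolerance, ~1e-14). At higher pressures the
  area-partitioned target outlets reverse one by one and the clamped index
  becomes piecewise linear: over the full 0–5000 Pa sweep on the reference
  tree the line fit leaves residuals of 1–3 percentage points, an overall
  linear declining trend rather than an exact line. Interior target-subtree
  segments can likewise turn retrograde below branch-level stall
  (intra-target steal between outlets held at different partitioned
  pressures); the clean threshold behaviour belongs to the *net target
  branch flow*.

## Boundary conditions

Defaults follow the study conditions: steady inlet flow 5 cm³/s, outlet
pressure 300 Pa, and a target-pressure sweep over 0, 1000, 2000, 3000,
4000, 5000 Pa. A target total pressure is *partitioned* over the target
outlets in direct proportion to their cross-sectional areas (the parts sum
to the total); the alternative reading — every target outlet held at the
full total — is available as `target_pressure_mode="common"`. The
partition convention concentrates low pressures on small outlets, which is
why the subtree's open-circuit (Thevenin) pressure coefficient κ is ≈ 1/10
on a 10-outlet target and the stall pressure is ≈ κ⁻¹ × the upstream
junction pressure.

The pulsatile waveform is a two-harmonic strictly positive flow,
`Q(t) = Q̄(1 + Σ aₘ sin(2πmt/T + φₘ))`, period 0.8 s (~75 bpm), mean
5 cm³/s. The base harmonic shape (amplitudes in ratio 0.45 : 0.18, phases
0 and π/2) is a generic arterial-like pulse chosen once; `default()`
rescales the amplitudes to a pulsatility index (Qmax−Qmin)/Q̄ of 1.0. All
parameters are exposed.

## Stall pressure and calibration

Flow "cessation" is defined operationally at a residual of 1 % of the
zero-pressure baseline target-branch flow (`rel_threshold`, configurable):
the approach to zero is linear, so an exact zero is never sampled. Because
the network is linear, the branch flow is exactly affine in the target
total pressure, `Q(P) = Q0(1 − P/P*)`, and:

- `find_stall_pressure` bisects to the threshold crossing (1 Pa interval
  tolerance);
- `analytic_stall_pressure` computes `P* = P_J/κ` in closed form by
  Thevenin reduction — κ from the target subtree under unit partitioned
  pressures, `P_J` from a conductance-split descent of the rest of the
  tree with the target subtree open — and returns `(1 − θ)P*` for a
  threshold θ. The two routes are independent (no shared linear solve) and
  agree within the bisection tolerance; this is the solver's structural
  cross-check.

`calibrate_stall_pressure` rescales the non-target *terminal* radii by one
global factor (Brent root finding on the analytic stall) until the stall
matches a requested value. The target subtree and the topology are
untouched so the EEI geometry is preserved; the rescaling intentionally
breaks Murray closure at the affected parents, which is a generator
guarantee, not a tree invariant. Under the partition convention the
reachable stall floor is ≈ κ⁻¹·(outlet pressure + internal path drop) —
about 3.5–4.7 kPa on default-geometry trees — because only terminal
resistances are scaled; the calibration-recovery tests therefore exercise
the wide-range round trip (1–20 kPa) in the `common` mode, where κ = 1 and
the floor is set by the outlet pressure itself. Calibration is idempotent
to 1e-6 in the scale.

## Synthetic tree generator

The generator emulates the hierarchy statistics the analysis depends on —
depth levels, outlet counts and areas, a designated target branch — not
patient geometry. The inlet→target path is laid down first so the target
branch sits at the exact requested depth (default 5) with the requested
target outlet count (default 10 of 43); at each path bifurcation a sibling
subtree peels off a random share of the remaining outlets, and subtrees
split recursively. Child radii follow Murray's law exactly
(`r_child = r_parent·w^(1/k)`, weights summing to 1, k = 3), with weights
proportional to downstream outlet counts times a log-uniform jitter
(asymmetry 0.3 by default). Segment lengths are 20 radii (no length data
exist for the source geometry; the ratio is configurable). The inlet
radius default, 2.31 mm, is back-solved from Re = 4ρQ/(πμD) with Q =
5 cm³/s and Re = 417. Everything is deterministic given the seed.

What the generator does *not* emulate: real branching angles, tortuosity,
segment-level length variation, anastomoses/collaterals, or imaging-derived
radii noise. Passing tests on generated trees therefore validate the
solver and the index algebra on realistic *hierarchies*, not agreement
with any patient's anatomy.

The packaged reference tree (`reference_fixture()`) is the seed-7 default
generation calibrated to a 5000 Pa stall at the study baseline; it is
committed as JSON and byte-stable (see `scripts/make_reference_tree.py`).

## Numerical choices

- Linear solves: `scipy.sparse.linalg.spsolve` on the reduced SPD system;
  junction mass residuals < 1e-10 relative, checked in tests against an
  independent dense brute-force assembly.
- Backflow/stall flow threshold: 1e-12 m³/s absolute; stall definition 1 %
  relative.
- Bisection: 1 Pa interval; calibration root find: Brent on log-scale,
  xtol 1e-14.
- Laminar guard: `LaminarFlowWarning` whenever any segment Re > 2300; the
  solver still returns the (formally exact) linear solution.
- Degenerate inputs: zero inlet flow is allowed (all flows at numerical
  zero); trees where the inlet feeds only the target branch admit no
  finite stall and raise.

## Problem sizes

The reference tree has 85 segments (44 junction unknowns); the default
study — six-condition pressure sweep, three-scale inflow sweep, stall
bisection (~40 solves), 64-sample pulsatile backflow study — runs in
seconds on one core. The seeded-tree batteries in the tests (20 trees for
the stall cross-check, 10 for calibration recovery) use the same default
topology.

## Known limitations

- No particle-level transport: microsphere size, density and inertia
  effects on bifurcation partitioning are not modelled; EEI is the
  advective flow-split proxy.
- Static outlet pressures: in reality embolization itself raises
  downstream pressure as particles lodge; a sweep approximates this as a
  quasi-static sequence.
- Rigid walls and Newtonian blood, as stated; both matter most in the
  smallest vessels.
- The quasi-steady pulsatile model understates phase lags; retrograde
  *fractions* are trustworthy, waveform *shapes* within a cycle less so.
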