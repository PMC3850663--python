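# Methods

## Model

One quarter of the at-term cervix is idealised as a planar mechanism: a
rigid link of length l (the cervical wall thickness) anchored by a pin
joint R1, joined at its far end through a pin R2 to a pair of orthogonal
sliding joints — P1, the radial half-opening of the endocervical canal, and
P2, the vertical descent of the balloon. The four generalized coordinates
(sP1, sP2, θR1, θR2) are bound by three holonomic loop-closure constraints;
the mechanism has one degree of freedom. The model carries one quarter of
the cervix mass, one quarter of the compliance, and one quarter of the
balloon traction. Friction and surface/contact deformation are not
modelled, the anchor point is fixed (valid for pre-labour only), and the
four quadrants are assumed exactly symmetric.

Parameters (SI internally; clinical units at the I/O boundary):

| parameter | default | unit | note |
|---|---|---|---|
| wall thickness l | 0.0225 | m | at-term wall of a 4.5 cm cervix, closed canal; link length |
| initial opening s_init | 0 | m | closed, no funnelling |
| quarter mass m | 0.00675 | kg | quarter of the 0.027 kg anatomical estimate |
| Jzz | (1/12) m l² = 2.85e-7 | kg·m² | thin-cylinder inertia about the link centre |
| B1 | 10 | N·m·s/rad | pin damping |
| B2 | 10 | N·s/m | sliding damping |
| g | 9.81 | m/s² | magnitude; sign is carried by the formulas |
| traction | 0.25 · 0.5 kg · g = 1.23 | N | quarter share of the 0.5 kg-force clinical pull |

The pivot inertia is M₃₃ = Jzz + m(l/2)², i.e. (1/3) m l² with the default
Jzz — the parallel-axis value for a centred link mass. The weight moment
about R1 is −m g (l/2) cosθ (the lever coefficient is configurable for
sensitivity analysis). The widely used parameter table for this model
prints a 0.07 kg mass that is inconsistent with its own inertia row by an
order of magnitude; the audit suite flags this known discrepancy as a
warning and checks Jzz against the printed 2.9e-7 kg·m² (2%), which the
0.00675 kg quarter mass reproduces.

## Kinematic reduction

The constraints admit the closed-form solution θR2 = −θR1,
sP1 = s_init + l(1−cosθ), sP2 = l sinθ with θ = θR1 ∈ [0, π/2] (the branch
containing the closed configuration; the θR2 = −θR1 + kπ branches are
discarded). All observables derive from it: dilation diameter = 2 sP1,
effacement = sP2. Since sinθ > 1−cosθ on (0, π/2), effacement always leads
dilation — the model's built-in version of the clinical observation that
the cervix thins before it opens. The reduced velocity map is the tangent
J = (l sinθ, l cosθ, 1, −1), which annihilates the constraint-reaction
directions, so reactions never enter the projected dynamics.

A note on the reaction-direction matrix Cᵀ: its columns agree with the rows
of the constraint Jacobian only up to the sign convention of the R2
reaction components (columns 1–2 flipped, column 3 equal on the constraint
manifold). The tests assert both facts — per-column agreement up to sign
against a finite-difference Jacobian, and exact annihilation of the
admissible tangent.

## Controller

Ripening is a feedback law on the *radius* dilation rate ṡP1 (half the
clinically quoted diameter rate). Both the traction force and the rate
setpoint ramp in over T = 1800 s with the cosine smoothstep
½ − ½cos(πt/T) — C¹, monotone, flat at both ends. The error
e = measured − desired, expressed in cm·hr⁻¹, is converted by proportional
gains (pin 20, sliding 100000, per scenario) into spring constants clamped
at zero. Stiffness therefore rises only when dilation runs ahead of the
setpoint; a lagging cervix is maximally soft. The error unit is a
configurable scale; cm·hr⁻¹ is the default because it is the clinical rate
unit and the one in which gains of this magnitude produce spring constants
of the magnitudes the scenarios exhibit. Integral or derivative terms and
gain schedules are out of scope.

Two protocol details are genuinely open and were fixed as package design
choices: the ramp shape (only known to be "smooth"; the cosine smoothstep
is the simplest C¹ candidate) and the single shared ramp duration for
traction and setpoint. The spring-constant *maxima* are sensitive to both:
once tracking holds, the peak spring constant is pinned by the quasi-static
torque balance at whatever opening angle the trajectory has reached when
traction approaches full strength, so protocols whose traction ramp leads
the setpoint ramp produce peaks several times larger at small angles.
Sensitivity studies over ramp timing (traction ramp 300–1800 s) moved K1max
across 0.10–0.62 N·m/rad and K2max (sliding-only) across 15000–55000 N/m,
while endpoint geometry and steady tracking were unaffected. The scenario
*ordering* — sliding-only needs a far larger spring constant than the
combined run, whose sliding peak in turn dwarfs the pin values, with the
pin peak identical whether or not the sliding spring helps — is robust to
all of these choices, as is the combined-run identity
K2max/K1max = gain ratio = 5000.

## Dynamics and numerics

Primary path (`REDUCED_ODE`): the single-DOF projection
M₃₃ θ̈ = Jᵀ F(θ, θ̇, t), a 2-state stiff ODE (fast eigenvalue ≈ −B1/M₃₃ ≈
−10⁷ s⁻¹, further increased by the feedback's velocity sensitivity),
integrated with SciPy's Radau IIA at the protocol tolerances
(abs = rel = 10⁻⁴ by default). Constraints are satisfied identically.

Validation path (`FULL_DAE`): all four coordinates with the singular mass
matrix and printed reaction directions, closed at acceleration level
(7×7 KKT solve per evaluation) under Baumgarte stabilization
(c̈ + 2α ċ + β² c = 0, α = β = 10 s⁻¹, configurable), integrated with BDF.
On this 8-state form Radau's Newton iteration thrashes against the fast
mode (~45× slower); BDF integrates the identical trajectory efficiently.
The cross-method audit runs both paths on one scenario at tightened
tolerances (10⁻⁶) and requires θ agreement within 10⁻⁵ of the quarter-turn,
constraint drift below 10⁻⁶, and spring maxima within 1%; measured values
on the default scenario are ~1×10⁻⁶, ~3×10⁻¹⁰ and ~8×10⁻⁷ respectively.
(At the scenario default 10⁻⁴ the agreement threshold would sit below
integrator error, which is why the audit tightens tolerances.)

Numerical choices that matter:

- **Per-component absolute tolerances.** The velocity states are of order
  10⁻⁶ m/s — far below a scalar atol of 10⁻⁴ — and the feedback gains
  (effectively 7.2×10⁶ and 3.6×10¹⁰ in SI per-unit-rate terms) amplify any
  velocity error the error test ignores. atol is therefore scaled per
  state by its characteristic magnitude (angles ~1 rad, rates ~ the
  commanded angular rate). With scalar tolerances the trajectory was
  visibly tolerance-dependent; with scaled ones, halving the tolerances
  changes the final diameter by ~5×10⁻¹⁰ relative.
- **Clamp regularisation.** max(e, 0) is a kink exactly where the springs
  disengage; the stiff solvers stall on it. Inside the integrator the
  clamp is replaced by the smooth-max (e + √(e²+δ²))/2 with δ = 10⁻⁴
  error units (a ten-thousandth of a cm/hr). The deviation is ≤ δ/2 at
  e = 0 and decays as δ²/4|e|, perturbing the spring peaks by < 0.1% and
  leaving a cosmetic K-floor of gain·δ/2 (10⁻³ N·m/rad for the pin) in
  the reported traces where the exact law gives zero. The public
  `feedback_springs` function keeps the exact hard clamp. Setting
  `feedback_smoothing: 0` restores it inside the solver as well.
- **Unilateral stop.** Early in the ramp the traction moment is below the
  weight moment and the closed cervix rests against its stop; the state is
  held at θ = 0 until the root-found lift-off instant (~190 s under
  defaults), from which integration starts at rest. The integrator-facing
  right-hand side also evaluates at coordinates clipped into the physical
  domain, which keeps implicit-solver trial iterates meaningful and
  realises the same stop if numerical noise dips θ below zero.
- **Termination.** Integration stops at the earlier of t_end or an
  event-located crossing of the termination diameter. The default
  termination diameter, 4.5 cm, equals the mechanism's geometric supremum
  2(s_init + l): the traction torque vanishes as cosθ → 0, so the opening
  approaches it exponentially (time constant B1/(l F) ≈ 6 min) and the
  event cannot fire; default runs end at t_end = 7 h with 4.498 cm. A
  termination diameter set strictly below the supremum is reached and
  event-located normally.
- **Output.** Trajectories are sampled from the dense solver output on a
  fixed 10 s grid (plus the ramp-end and final instants), so CSVs are
  independent of step-size history. Reactions are recovered per sample by
  least squares on the consistent 4×3 system Cᵀf = F − M q̈.

The run summary reports two rates: `mean_postramp_diameter_rate_cm_per_hr`,
the endpoint secant from ramp end to termination, and
`steady_tracking_rate_cm_per_hr`, the secant over the central plateau
(from twice the ramp duration to the six-hour mark). The two differ by
construction: the endpoint secant spans the ramp-in transient and the
terminal flattening toward the geometric opening limit, and lands ~4% below
the setpoint; the plateau secant is the quantity the setpoint controls
(0.6935 vs 0.692 cm/hr on the default run, +0.2%).

## What the simulations do and do not show

The default scenarios are synthetic study conditions, not patient data: a
rigid, exactly symmetric quarter mechanism, a constant hanging-mass
traction, a prescribed clinical-rate setpoint, and lumped viscoelasticity.
Passing tests show that the mechanism, reduction, controller and both
integration paths implement the stated equations self-consistently and
reproduce the study's endpoint geometry, tracking behaviour and scenario
ordering; they say nothing about inter-patient variability, tissue
constitutive behaviour, friction/contact at the balloon surface, or
funnelled cervical geometries (s_init > 0 is supported numerically but not
validated against data). The timescale can be compressed for phantom work
(higher setpoint rates terminate proportionally earlier), but such
accelerated runs are uncalibrated.

## Known limitations

- The spring-constant maxima depend on the unprinted details of the ramp
  protocol (see Controller above); only their ordering and the
  combined-run gain-ratio identity are protocol-robust.
- The quasi-static spring oracle is singular at θ = 0 (both springs have
  zero stroke while the traction torque is maximal) and is only used for
  post-ramp audit windows.
- The DAE path's directional derivative of the constraint Jacobian is a
  central finite difference (error ~10⁻¹⁰), adequate for the drift bounds
  audited but not exact.
- Simulation requires the non-negativity clamp; the unclamped law is
  exposed for controller-level analysis only, since a negative commanded
  stiffness is not realisable by a passive spring.
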