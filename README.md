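# cervixsim

Multibody simulation of cervical dilation and effacement during pre-labour
under the traction of an induction balloon dilator, with feedback-controlled
time-varying compliance.

## The problem

Labour is induced in over a fifth of births; one of the oldest and safest
methods places a balloon catheter (a Foley catheter) above the interior os
of the cervix and applies a small traction force (~0.5 kg-force, taped to
the thigh). The cervix responds by *softening*: it effaces (thins) and
dilates (opens) at a near-constant clinical rate until, at roughly 4–5 cm of
dilation, the balloon is expelled and active labour begins. There is no
simple analytic model of this interaction — existing descriptions are either
qualitative or full finite-element computations. `cervixsim` implements a
minimal mechanism model of it, intended for exploring induction dynamics in
simulation and as the control law for electromechanical cervix phantoms used
in clinical training and dilator testing.

## The model

By symmetry, one quarter of the at-term cervix (wall thickness
l = 2.25 cm, quarter mass m = 6.75 g) is a single rigid link anchored to the
uterus/endopelvic fascia by a pin joint R1 (spring–damper K1, B1) and
connected through a second pin R2 to two orthogonal sliders: P1, the radial
half-opening of the canal (spring–damper K2, B2), and P2, the vertical
balloon descent, which carries the quarter share of the traction,
F = 0.25 · 0.5 kg · g = 1.23 N. The dynamics are the constrained multibody
system

    M q̈ + Cᵀ f = F(q, q̇, t),      g(q) = 0,

with four generalized coordinates q = (sP1, sP2, θR1, θR2) and three loop-
closure constraints, leaving one degree of freedom. The constraints resolve
in closed form (θR2 = −θR1, sP1 = s_init + l(1−cos θ), sP2 = l sin θ), so the
primary integration path is the single-DOF projection

    M₃₃ θ̈ = l sinθ (−K2(sP1−s_init) − B2 ṡP1) + l cosθ F_tr(t)
            − m g (l/2) cosθ − K1 θ − B1 θ̇,      M₃₃ = Jzz + m(l/2)²,

a very stiff ODE (B1/M₃₃ ≈ 10⁷ s⁻¹) integrated implicitly. A full
stabilized-DAE path integrates all four coordinates against the printed
matrices as an independent validation route.

Cervical *ripening* is modelled as feedback-controlled compliance: the
tracking error of the radius dilation rate (setpoint 0.692 cm·hr⁻¹ diameter
rate, i.e. 0.346 cm·hr⁻¹ radius rate, ramped in smoothly over the first half
hour together with the traction) is converted through proportional gains
(20 N·s·rad⁻¹ pin, 100000 N·s·m⁻² sliding; error taken in cm·hr⁻¹) into
non-negative spring constants K1(t), K2(t). When dilation runs ahead of the
setpoint the cervix stiffens; otherwise the springs relax toward zero and
traction advances dilation — the softening that paces pre-labour. Three
scenarios are built in: pin spring only, sliding spring only, and both.

## Worked example

```bash
cervixsim simulate --out out/
```

prints, for the default pin-joint scenario:

```
final dilation 4.498 cm, effacement 2.250 cm at 7.000 h (t_end_reached); K1_max 0.102 N·m/rad, K2_max 0 N/m
```

and writes `out/timeseries.csv` (states, observables, spring constants and
constraint reactions every 10 s), `out/summary.json` and
`out/cervicogram.csv` (time vs dilation, the clinical plot). Reading the
numbers: over seven simulated hours the canal opens to 4.50 cm diameter
(the full cervical width — the balloon-expulsion point) with 2.25 cm of
effacement (100%, the full wall thickness), and the steady dilation rate
held by the controller is 0.694 cm/hr against the 0.692 cm/hr setpoint
(`steady_tracking_rate_cm_per_hr` in the summary). The pin spring peaks at
0.102 N·m/rad shortly before the traction ramp completes — the instant the
spring must counter the largest traction torque the tracking trajectory
exposes — and decays thereafter: the ripening trajectory.

Scenario files are small YAML documents (clinical units); any omitted key
keeps its study default:

```yaml
controller:
  mode: both             # pin | sliding | both
  desired_diameter_rate_cm_per_hr: 1.2
solver:
  t_end_hours: 4
```

`cervixsim sweep --gains-pin 10,20,40` runs gain grids;
`cervixsim audit` checks a scenario's parameter-table consistency and the
agreement between the reduced and full-DAE integration paths.

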