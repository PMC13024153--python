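# Methods

## Model and assumptions

The package models an open-kinetic-chain, single-joint strengthening
exercise as a planar rigid-body problem. The moving limb (for the knee-
extension case, the shank+foot system) rotates about a fixed joint axis J;
its centre of mass C lies on the longitudinal axis. A single dominant
agonist acts through a tendon with moment arm aF(θ) and traction angle γ(θ);
antagonist and synergist forces are neglected (valid for quadriceps-dominant
knee extension except near terminal extension, where hamstring co-contraction
would add a small PCL-loading shear — neglecting it makes the ACL-loading
estimate conservative). All external loads, including limb weight, are
reduced to a single equivalent resistance R applied on the longitudinal axis
at distance rP, at angle β ∈ (−90°, 90°) to the perpendicular of the segment;
this reduction is exact for any planar force system, which is why gravity is
not modelled separately.

The moment balance about J gives the muscle force

    F = (I·θ̈ + R·rP·cos β − τφ) / aF,

and the force balance on the segment gives the joint reaction components

    φ_shear = m·rC·θ̈ − F·sin γ + R·cos β,
    φ_axial = −m·rC·θ̇² + F·cos γ + R·sin β,

with φ_shear > 0 PCL-loading and φ_axial > 0 compressive. Eliminating F
yields closed forms in which each component splits into velocity,
acceleration, resistance and passive terms; the two computation paths are
implemented independently (`reaction_from_muscle ∘ muscle_force` vs
`reaction_closed_form`) and their agreement to 1e-10 relative is enforced by
property tests — each is the oracle for the other.

A computed F < 0 means the single-agonist model is outside its validity
(antagonist torque would be required); it is flagged
(`MuscleForce.antagonist_demand`), never clamped, and the reaction computed
from it is reported as-is.

## Inverse solvers

The strengthening stimulus is fixed by the resistance-torque profile
τ_opt(θ) > 0 through the constraint R·rP·cos β = τ_cmd. Substituting
R·cos β = τ_cmd/rP makes the shear closed form linear in 1/rP, and at fixed
rP the axial closed form is linear in tan β, so arbitrary shear/axial targets
are solved exactly with no iteration and no tolerance tuning:

1. shear target → 1/rP = sin γ/aF + [shear* − (m·rC − I·sin γ/aF)·θ̈
   − (sin γ/aF)·τφ]/τ_cmd (otherwise rP defaults to the distal pad, rP_max —
   the conventional machine configuration);
2. axial target → tan β = rP·[axial* + m·rC·θ̇² − (cos γ/aF)·(I·θ̈ − τφ)]/τ_cmd
   − rP·cos γ/aF (otherwise β = 0);
3. R = τ_cmd/(rP·cos β).

The ordering (rP before β) matters because rP enters the axial equation; it
is fixed, not configurable. Every solve is verified by plugging the
configuration back into the forward model. Dynamic repetitions additionally
use the inertial torque compensation τ_cmd = τ_opt − I·θ̈, which keeps the
muscle force on its quasi-static target; τ_cmd ≤ 0 would require the machine
to assist and is infeasible by design.

Infeasibility (rP outside bounds, required 1/rP ≤ 0 in the always-PCL
regime, β at its open bound, R above R_max, assistive τ_cmd) is data in
plans — per-sample flags with the violated constraint named — while
single-point solves raise `InfeasibleConfiguration` unless `strict=False`.
When bounds bind, no parameter "absorbs" the violation; the sample is simply
reported infeasible.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| mass_fraction | 0.061 | – | shank+foot fraction of body mass (Winter-style tables; ≈6%) |
| com_fraction | 0.606 | – | knee-to-COM distance / segment length |
| gyration_fraction_proximal | 0.735 | – | radius of gyration about the knee / segment length |
| segment length | 0.43 | m | tibial length of the 1.75 m reference subject; scaled ∝ stature otherwise, or pinned explicitly |
| γ(θ) | +20° → −10° linear | deg | traction-angle endpoints over flexion 0–120° |
| aF anchors | 0.0470 / 0.0481 / 0.0550 / 0.0570 | m | at flexion 0 / 16.4 / 60 / 120°; see calibration note |
| τφ end magnitude | 10 | N·m | physiologically grounded end-range passive moment for the knee (literature range ≈ 8–15 N·m) |
| τφ engage angle | 20 | deg flexion | passive moment negligible mid-range |
| rP bounds | 0.05–0.40 | m | pad must sit on the shank (tibial length ≈ 0.43 m) |
| ε_sin | 1e-6 | – | sin γ guard below which the zero-shear distance is the ∞ sentinel |
| profile sampling | 1 kHz | – | representative of a real-time control loop |

The reference subject (1.75 m, 75 kg) gives m = 4.575 kg, rC = 0.2606 m,
I = 0.457 kg·m². All defaults are overridable through the YAML run config
(sections `subject`, `fractions`, `anatomy`, `passive_torque`, `bounds`);
unknown keys are rejected and every error names the field. Each loaded
config is logged with a content hash for provenance.

### Anatomy calibration

The true moment-arm and traction-angle curves for the knee extensor
mechanism are measured quantities not shipped with this package; the default
table is a **calibrated reference anatomy**: γ linear between the published
endpoint values (+20° at full extension, −10° at 120° flexion), and four aF
anchors pinned so that the model equations reproduce the case study's worked
numbers exactly. Each anchor was verified by hand-evaluating the
corresponding closed-form term before being frozen. The "end of the range of
motion" evaluation point is flexion 16.4°, where the linear γ table gives
γ = 15.9°: the worked end-range values imply tan γ = 57/200 ≈ 0.285 there,
which is inconsistent with γ = 20° at terminal extension itself, so the
evaluation point is placed where the linear table attains that angle. Users
with subject-specific geometry should supply their own table
(`anatomy: path.yaml`, linear or monotone-cubic interpolation).

### Angle conventions

The public API uses the knee flexion angle in degrees (0° = full extension,
ROM 0–120°). The dynamics equations internally use the complementary joint
angle θ = 90° − flexion in radians, so θ̇ and θ̈ (columns `omega_deg_s`,
`alpha_deg_s2`) are positive while the knee accelerates into extension.
Statements about the "final 50°" of the movement refer to the flexion angle:
with the reference anatomy, the zero-shear distance aF/sin γ fits the 0.40 m
pad limit only below ≈49° of flexion, and for larger flexion angles sin γ ≤ 0
makes the shear PCL-loading for every admissible pad position.

## Motion generators and what they do not emulate

`quasi_static_profile` sweeps the ROM with θ̇ = θ̈ ≡ 0 — the idealized slow
repetition; its sample time is a sweep parameterization, which is why the
finite-difference validator skips identically-zero rate channels.
`parabolic_profile` models an explosive repetition with
θ̇(t) = v·4t(T−t)/T², giving peak acceleration 4v/T at both ends and a total
excursion of (2/3)·v·T by exact integration. The reference explosive scenario
(500°/s over 0.5 s) implies a 166.7° excursion that exceeds the 120° ROM; it
is kept as a parameter scenario — the generator warns, and batch evaluation
clamps anatomy lookups at the ROM bounds rather than clamping the profile.

Neither generator emulates measured human motion: no tremor, no measurement
noise, no asymmetric acceleration profiles, no filtering artifacts from
numerical differentiation of captured trajectories. Passing tests therefore
demonstrate the correctness of the analytical machinery on idealized
kinematics, not robustness to real capture pipelines (which would sit
upstream of this package).

The passive-moment model is a declared choice: the underlying magnitude is
supported by the literature but its angle dependence is not specified there,
so a linear (optionally smoothstep) ramp from the engage angle to terminal
extension is used. The worked end-range values apply the full 10 N·m at the
evaluation point directly, as in the source analysis, while the ramp serves
continuous curves; the two coincide at terminal extension.

## Numerical choices

* Everything is closed-form; the only root find is locating curve crossings
  for the case-study figures (Brent's method on a bracketing interval).
* Interpolation reproduces anchors bit-exactly (asserted); linear is the
  default, PCHIP optional.
* The zero-shear distance is reported as +∞ wherever sin γ ≤ 1e-6 rather
  than overflowing, preserving the always-PCL classification.
* Bounds checks use 1e-12 absolute slack so solutions sitting exactly on a
  bound are feasible.
* Term breakdowns sum to the component values exactly (same additions, no
  re-derivation).

## Problem sizes

All computations are desk-scale: the case-study curves use 241-point grids,
plans sweep ≤ a few hundred samples, and the randomized equivalence and
plug-back checks use 10⁴ seeded cases each (seeds fixed in the tests; the
model itself has no randomness). The full suite runs in a few seconds.

## Known limitations

* Single dominant agonist; no co-contraction, EMG-driven estimation or
  muscle redundancy. Multi-joint (mechanically indeterminate) tasks are out
  of scope.
* Fixed joint centre and rigid segment; no joint-centre migration, no
  distribution of net shear among individual ligaments (the net anterior
  restraint is predominantly the ACL, but reporting stays at net-shear
  level).
* Planar (sagittal) mechanics only; varus–valgus and rotational loads are
  not represented.
* Actuator dynamics, latency and sensor noise of a physical machine are not
  modelled; the solvers output the ideal configuration trajectory.
* One published worked value — an onset shear of ≈24 N at 4000°/s² — is not
  reproducible from the model's own acceleration factor (m·rC − I·sin γ/aF ≈
  2.58 kg·m in deep flexion gives ≈180 N); it is documented as a discrepancy
  and excluded from the regression table.
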