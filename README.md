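# jointload

Analytical control of tibiofemoral joint reaction forces during single-joint
strengthening exercise.

Strength machines with electromechanical actuation can vary not just the
resistance magnitude *R* during a repetition, but also its direction *β* and
its point of application *r<sub>P</sub>* on the limb. `jointload` implements a
planar rigid-body model of an open-kinetic-chain, single-joint exercise
(knee extension being the worked case) that makes this controllability
useful: it computes the shear and axial components of the joint reaction
force from the kinematics and the resistance configuration, and inverts those
relations in closed form to choose (R, β, r<sub>P</sub>) so that targeted
reaction components are nulled — eliminating, for instance, the ACL-loading
shear force — **without changing the prescribed resistance-torque profile**
that defines the strengthening stimulus. It is aimed at biomechanists,
rehabilitation engineers and designers of adaptive resistance equipment.

## Model

The moving limb (shank+foot, mass *m*, knee-to-COM distance *r<sub>C</sub>*,
moment of inertia *I* about the knee) is driven by a single dominant agonist
(the quadriceps via the patellar tendon, moment arm *a<sub>F</sub>(θ)*,
traction angle *γ(θ)*) against an equivalent resistance *R* applied at
distance *r<sub>P</sub>* at angle *β* to the perpendicular of the segment.
The moment balance gives the muscle force

```
F = (I·θ̈ + R·rP·cos β − τφ) / aF
```

(τφ ≤ 0 is the end-range passive joint moment), and eliminating *F* from the
force balance yields the reaction components as four additive terms each:

```
φ_shear = (m·rC − I·sin γ/aF)·θ̈ + R·cos β·(1 − rP·sin γ/aF) + (sin γ/aF)·τφ
φ_axial = −m·rC·θ̇² + (cos γ/aF)·I·θ̈ + R·(sin β + (cos γ/aF)·rP·cos β) − (cos γ/aF)·τφ
```

with φ_shear > 0 PCL-loading (< 0 ACL-loading) and φ_axial > 0 compressive.
Under the torque constraint `R·rP·cos β = τ_cmd` these are **linear in 1/rP
and tan β respectively**, so the inverse problem is solved exactly:

* zero axial (quasi-static): `tan β / rP = −cos γ / aF`;
* zero shear (quasi-static): `rP = aF / sin γ`, feasible only where
  sin γ > 0 and the distance fits on the segment (below ≈50° of flexion with
  the reference anatomy — elsewhere a PCL-loading shear persists for every
  admissible pad position);
* dynamic targets: closed-form chain rP → β → R, with the commanded torque
  `τ_cmd = τ_opt − I·θ̈` compensating the inertial torque so the muscle force
  stays on its prescribed profile.

## Worked example

```sh
jointload casestudy --out-dir out/
```

writes the reference curves (`figure2.csv`–`figure4.csv`) and prints the
worked-value regression table for the 1.75 m / 75 kg reference subject:

```
                      label    computed  reference   units  relative_deviation
        velocity_traction_N   90.787681       90.0       N            0.008752
 acceleration_compression_N  551.209444      550.0       N            0.002199
passive_axial_compression_N  199.946218      200.0       N            0.000269
        passive_acl_shear_N   56.956179       57.0       N            0.000769
   beta_zero_axial_rP40_deg  -82.873087      -83.0     deg            0.001529
   beta_zero_axial_rP05_deg  -44.992295      -45.0     deg            0.000171
   peak_acceleration_deg_s2 4000.000000     4000.0 deg/s^2            0.000000
shear inertial factor changes sign at flexion 48.1 deg; zero-shear strategy feasible below flexion 49.4 deg
```

Reading the rows: a 500°/s peak angular velocity distracts the joint by
~91 N (the centripetal term); a 4000°/s² onset acceleration in deep flexion
compresses it by ~551 N; a 10 N·m end-range passive moment adds ~200 N of
compression and ~57 N of ACL-loading shear; and nulling the axial component
quasi-statically at the end of the range requires pulling at β ≈ −83° with a
distal pad (r<sub>P</sub> = 0.40 m) but only β ≈ −45° with a proximal one
(0.05 m).

From Python:

```python
import jointload as jl

seg = jl.segment_inertia(jl.REFERENCE_SUBJECT)   # m=4.575 kg, I=0.457 kg·m²
anat = jl.default_table()

plan = jl.plan_exercise(
    jl.quasi_static_profile(n_samples=121),
    jl.TorqueProfile.constant(30.0),
    "zero_shear", seg, anat,
)
print(f"{plan.feasible_fraction:.0%} of the sweep can be made shear-free")
# -> 41% of the sweep can be made shear-free  (flexion ≲ 49°)
```

Other subcommands: `jointload profile` (generate quasi-static or parabolic
motion CSVs), `jointload evaluate` (forward reaction components with per-term
breakdown), `jointload plan` (per-sample inverse solves for the plain /
zero-shear / zero-axial / zero-both modes). A YAML config (`--config`) can
override the subject, inertial fractions, anatomy table, passive-torque model
and solver bounds; see `docs/methods.md`.

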