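"""Forward model of the tibiofemoral joint reaction during knee extension.

The moving limb is a rigid shank+foot segment rotating about a fixed knee
axis, driven by a single dominant agonist (the quadriceps, acting through the
patellar tendon) against an external resistance reduced to a single force R
applied on the longitudinal axis at distance rP from the joint, at angle β to
the perpendicular of the segment. Two computation paths are provided:

* the two-step path — muscle force from the moment balance about the knee,

      F = (I·θ̈ + R·rP·cosβ − τϕ) / aF,

  then the reaction components from the force balance on the segment,

      φ_shear = m·rC·θ̈ − F·sinγ + R·cosβ,
      φ_axial = −m·rC·θ̇² + F·cosγ + R·sinβ;

* the closed-form path, obtained by eliminating F, which splits each
  component into velocity, acceleration, resistance and passive terms:

      φ_shear = (m·rC − I·sinγ/aF)·θ̈ + R·cosβ·(1 − rP·sinγ/aF)
                + (sinγ/aF)·τϕ,
      φ_axial = −m·rC·θ̇² + (cosγ/aF)·I·θ̈
                + R·(sinβ + (cosγ/aF)·rP·cosβ) − (cosγ/aF)·τϕ.

The two paths are algebraically identical; both are implemented independently
so each can serve as an oracle for the other. Sign conventions: positive
shear is PCL-loading (anterior force of the femur on the tibia), negative
shear is ACL-loading; positive axial is compression.

Gravity is not modelled separately: a planar force system reduces to a single
equivalent resistance, so limb weight is folded into (R, β, rP) by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .anatomy import FLEXION_MAX_DEG, FLEXION_MIN_DEG, AnatomyTable
from .anthropometry import SegmentInertia
from .kinematics import JointState, MotionProfile
from .passive_torque import PassiveTorqueModel

__all__ = [
    "ResistanceConfig",
    "ReactionTerms",
    "JointReaction",
    "MuscleForce",
    "muscle_force",
    "reaction_from_muscle",
    "reaction_closed_form",
    "shear_inertial_factor",
    "evaluate_profile",
]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class ResistanceConfig:
    """External resistance: magnitude R (N), direction β (deg), distance rP (m).

    β = 0 means the resistance acts perpendicular to the longitudinal axis of
    the segment; β must lie strictly inside (−90°, 90°) so the resistance
    always opposes extension when R·cosβ > 0.
    """

    R_n: float
    beta_deg: float = 0.0
    rP_m: float = 0.40

    def __post_init__(self) -> None:
        if self.R_n < 0:
            raise ValueError(f"R_n must be >= 0, got {self.R_n}")
        if not -90.0 < self.beta_deg < 90.0:
            raise ValueError(
                f"beta_deg must lie strictly inside (-90, 90), got {self.beta_deg}"
            )
        if not self.rP_m > 0:
            raise ValueError(f"rP_m must be > 0, got {self.rP_m}")

    @property
    def torque_nm(self) -> float:
        """Resistance torque R·rP·cosβ about the joint (N·m)."""
        return self.R_n * self.rP_m * math.cos(self.beta_deg * _DEG)


@dataclass(frozen=True)
class ReactionTerms:
    """Additive decomposition of one reaction component (N)."""

    velocity: float = 0.0
    acceleration: float = 0.0
    resistance: float = 0.0
    passive: float = 0.0
    muscle: float = 0.0  # populated only by the two-step path

    @property
    def total(self) -> float:
        return (
            self.velocity
            + self.acceleration
            + self.resistance
            + self.passive
            + self.muscle
        )


@dataclass(frozen=True)
class JointReaction:
    """Shear and axial tibiofemoral reaction components with term breakdown.

    shear > 0 is PCL-loading, shear < 0 is ACL-loading; axial > 0 is
    compression, axial < 0 is traction (joint distraction).
    """

    shear_n: float
    axial_n: float
    shear_terms: ReactionTerms = field(default_factory=ReactionTerms)
    axial_terms: ReactionTerms = field(default_factory=ReactionTerms)


@dataclass(frozen=True)
class MuscleForce:
    """Patellar-tendon force magnitude and its traction angle at evaluation.

    A negative magnitude means the single-agonist model would need antagonist
    action to realise the motion; it is flagged, not clamped.
    """

    F_n: float
    gamma_deg: float

    @property
    def antagonist_demand(self) -> bool:
        return self.F_n < 0


def _anatomy_at(anat: AnatomyTable, flexion_deg: float, clamp: bool):
    if clamp:
        flexion_deg = min(max(flexion_deg, FLEXION_MIN_DEG), FLEXION_MAX_DEG)
    gamma = anat.gamma_at(flexion_deg) * _DEG
    aF = anat.aF_at(flexion_deg)
    return gamma, aF


def muscle_force(
    state: JointState,
    res: ResistanceConfig | None,
    seg: SegmentInertia,
    anat: AnatomyTable,
    tau_phi_nm: float = 0.0,
    clamp_rom: bool = False,
) -> MuscleForce:
    """Muscle force from the moment balance about the joint axis.

    F = (I·θ̈ + R·rP·cosβ − τϕ) / aF, with θ̈ in rad/s².
    """
    gamma, aF = _anatomy_at(anat, state.flexion_deg, clamp_rom)
    if aF <= 0:
        raise ValueError(f"moment arm must be positive, got {aF}")
    res_torque = res.torque_nm if res is not None else 0.0
    F = (seg.i_kgm2 * state.alpha_rad_s2 + res_torque - tau_phi_nm) / aF
    return MuscleForce(F_n=F, gamma_deg=gamma / _DEG)


def reaction_from_muscle(
    state: JointState,
    muscle: MuscleForce,
    res: ResistanceConfig | None,
    seg: SegmentInertia,
) -> JointReaction:
    """Reaction components from the force balance, given the muscle force."""
    gamma = muscle.gamma_deg * _DEG
    R = res.R_n if res is not None else 0.0
    beta = (res.beta_deg if res is not None else 0.0) * _DEG

    shear_terms = ReactionTerms(
        acceleration=seg.m_kg * seg.r_c_m * state.alpha_rad_s2,
        resistance=R * math.cos(beta),
        muscle=-muscle.F_n * math.sin(gamma),
    )
    axial_terms = ReactionTerms(
        velocity=-seg.m_kg * seg.r_c_m * state.omega_rad_s**2,
        resistance=R * math.sin(beta),
        muscle=muscle.F_n * math.cos(gamma),
    )
    return JointReaction(
        shear_n=shear_terms.total,
        axial_n=axial_terms.total,
        shear_terms=shear_terms,
        axial_terms=axial_terms,
    )


def reaction_closed_form(
    state: JointState,
    res: ResistanceConfig | None,
    seg: SegmentInertia,
    anat: AnatomyTable,
    tau_phi_nm: float = 0.0,
    clamp_rom: bool = False,
) -> JointReaction:
    """Reaction components with the muscle force eliminated analytically.

    Populates the four-term breakdown (velocity, acceleration, resistance,
    passive) of each component; the terms sum exactly to the component value.
    """
    gamma, aF = _anatomy_at(anat, state.flexion_deg, clamp_rom)
    if aF <= 0:
        raise ValueError(f"moment arm must be positive, got {aF}")
    sin_g, cos_g = math.sin(gamma), math.cos(gamma)
    R = res.R_n if res is not None else 0.0
    beta = (res.beta_deg if res is not None else 0.0) * _DEG
    rP = res.rP_m if res is not None else 0.0
    alpha = state.alpha_rad_s2
    omega = state.omega_rad_s

    shear_terms = ReactionTerms(
        acceleration=(seg.m_kg * seg.r_c_m - seg.i_kgm2 * sin_g / aF) * alpha,
        resistance=R * math.cos(beta) * (1.0 - rP * sin_g / aF),
        passive=(sin_g / aF) * tau_phi_nm,
    )
    axial_terms = ReactionTerms(
        velocity=-seg.m_kg * seg.r_c_m * omega**2,
        acceleration=(cos_g / aF) * seg.i_kgm2 * alpha,
        resistance=R * (math.sin(beta) + (cos_g / aF) * rP * math.cos(beta)),
        passive=-(cos_g / aF) * tau_phi_nm,
    )
    return JointReaction(
        shear_n=shear_terms.total,
        axial_n=axial_terms.total,
        shear_terms=shear_terms,
        axial_terms=axial_terms,
    )


def shear_inertial_factor(
    seg: SegmentInertia, anat: AnatomyTable, flexion_deg: float
) -> float:
    """Acceleration sensitivity of the shear component, m·rC − I·sinγ/aF (kg·m).

    This factor multiplies θ̈ in the shear decomposition; it changes sign
    within the range of motion (positive in deep flexion, negative near
    terminal extension), so angular acceleration loads the PCL in both the
    initial and final phases of a continuous repetition.
    """
    ratios = anat.lever_ratios(flexion_deg)
    return seg.m_kg * seg.r_c_m - seg.i_kgm2 * ratios.sin_over_aF


def evaluate_profile(
    profile: MotionProfile,
    seg: SegmentInertia,
    anat: AnatomyTable,
    resistance=None,
    passive: PassiveTorqueModel | None = None,
) -> pd.DataFrame:
    """Batch closed-form evaluation of a motion profile.

    ``resistance`` may be ``None`` (unresisted), a fixed
    :class:`ResistanceConfig`, or a callable ``state -> ResistanceConfig``.
    Flexion angles beyond the range of motion (a generated profile may
    overshoot) are clamped for anatomy lookups.
    """
    rows = []
    for t, state in zip(profile.t_s, profile.states):
        res = resistance(state) if callable(resistance) else resistance
        flex_clamped = min(max(state.flexion_deg, FLEXION_MIN_DEG), FLEXION_MAX_DEG)
        tau_phi = passive.tau_phi(flex_clamped) if passive is not None else 0.0
        muscle = muscle_force(state, res, seg, anat, tau_phi, clamp_rom=True)
        reaction = reaction_closed_form(state, res, seg, anat, tau_phi, clamp_rom=True)
        rows.append(
            {
                "t_s": t,
                "flexion_deg": state.flexion_deg,
                "F_N": muscle.F_n,
                "shear_N": reaction.shear_n,
                "axial_N": reaction.axial_n,
                "shear_vel": reaction.shear_terms.velocity,
                "shear_acc": reaction.shear_terms.acceleration,
                "shear_res": reaction.shear_terms.resistance,
                "shear_pas": reaction.shear_terms.passive,
                "axial_vel": reaction.axial_terms.velocity,
                "axial_acc": reaction.axial_terms.acceleration,
                "axial_res": reaction.axial_terms.resistance,
                "axial_pas": reaction.axial_terms.passive,
            }
        )
    return pd.DataFrame(rows)
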