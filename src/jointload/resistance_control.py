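"""Inverse resistance solvers: choose (R, β, rP) to control joint loading.

The strengthening stimulus is fixed by the resistance-torque profile
τ_opt(θ): every admissible configuration must satisfy R·rP·cosβ = τ_cmd,
where τ_cmd is the commanded torque (τ_opt corrected for the inertial torque
I·θ̈ so the muscle force stays at its quasi-static target). Within that
constraint the application distance rP and direction β are free, and the
reaction decomposition is linear in 1/rP (shear) and tanβ (axial), so both
the zero-shear and zero-axial conditions — and arbitrary shear/axial targets
— admit closed-form solutions. No iteration is involved anywhere.

Quasi-static special cases:

* zero axial:  tanβ / rP = −cosγ / aF   (β always in (−90°, 0));
* zero shear:  rP = aF / sinγ           (feasible only where sinγ > 0 and the
  distance fits on the segment; elsewhere a PCL-loading shear persists for
  every admissible rP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .anatomy import EPS_SIN, AnatomyTable
from .anthropometry import SegmentInertia
from .dynamics import JointReaction, ResistanceConfig, reaction_closed_form
from .kinematics import JointState, MotionProfile
from .passive_torque import PassiveTorqueModel

__all__ = [
    "TorqueProfile",
    "SolverBounds",
    "SolveResult",
    "ControlPlan",
    "InfeasibleConfiguration",
    "beta_zero_axial",
    "rp_zero_shear_quasistatic",
    "commanded_torque",
    "solve_configuration",
    "plan_exercise",
    "PLAN_MODES",
]

_DEG = math.pi / 180.0

PLAN_MODES = ("plain", "zero_shear", "zero_axial", "zero_both")


class InfeasibleConfiguration(ValueError):
    """Raised by strict single-point solves when a bound or sign constraint binds."""

    def __init__(self, violation: str):
        super().__init__(violation)
        self.violation = violation


@dataclass(frozen=True)
class TorqueProfile:
    """Prescribed resistance-torque profile τ_opt(flexion), N·m, positive.

    Either a constant torque or a tabulated (flexion_deg, torque_nm) curve
    interpolated linearly.
    """

    constant_nm: float | None = None
    flexion_deg: tuple[float, ...] | None = None
    torque_nm: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.constant_nm is not None:
            if self.constant_nm <= 0:
                raise ValueError("torque profile must be positive over the ROM")
        elif self.flexion_deg is not None and self.torque_nm is not None:
            if len(self.flexion_deg) != len(self.torque_nm) or len(self.flexion_deg) < 2:
                raise ValueError("tabulated profile needs >= 2 matching rows")
            if not all(v > 0 for v in self.torque_nm):
                raise ValueError("torque profile must be positive over the ROM")
        else:
            raise ValueError("provide constant_nm or (flexion_deg, torque_nm)")

    @classmethod
    def constant(cls, torque_nm: float) -> "TorqueProfile":
        return cls(constant_nm=torque_nm)

    @classmethod
    def from_table(
        cls, flexion_deg: Sequence[float], torque_nm: Sequence[float]
    ) -> "TorqueProfile":
        order = np.argsort(flexion_deg)
        return cls(
            flexion_deg=tuple(float(flexion_deg[i]) for i in order),
            torque_nm=tuple(float(torque_nm[i]) for i in order),
        )

    def tau_at(self, flexion_deg: float) -> float:
        if self.constant_nm is not None:
            return self.constant_nm
        return float(np.interp(flexion_deg, self.flexion_deg, self.torque_nm))


@dataclass(frozen=True)
class SolverBounds:
    """Feasibility bounds on the resistance configuration.

    Defaults: rP within 5–40 cm (the resistance pad must sit on the shank,
    tibial length ≈ 43 cm), unbounded R, β strictly inside (−90°, 90°).
    """

    rP_min_m: float = 0.05
    rP_max_m: float = 0.40
    R_max_n: float = math.inf
    beta_limit_deg: float = 90.0

    def __post_init__(self) -> None:
        if not 0 < self.rP_min_m < self.rP_max_m:
            raise ValueError(
                f"need 0 < rP_min_m < rP_max_m, got ({self.rP_min_m}, {self.rP_max_m})"
            )
        if self.R_max_n <= 0:
            raise ValueError("R_max_n must be > 0")
        if not 0 < self.beta_limit_deg <= 90.0:
            raise ValueError("beta_limit_deg must lie in (0, 90]")


DEFAULT_BOUNDS = SolverBounds()


def beta_zero_axial(flexion_deg: float, rP_m: float, anat: AnatomyTable) -> float:
    """Resistance direction β (deg) nulling the axial reaction quasi-statically.

    β = atan(−rP·cosγ/aF); always in (−90°, 0) since cosγ > 0 over the ROM.
    Assumes θ̇ = θ̈ ≈ 0 and negligible passive torque.
    """
    if rP_m < 0:
        raise ValueError("rP_m must be >= 0")
    ratios = anat.lever_ratios(flexion_deg)
    return math.atan(-rP_m * ratios.cos_over_aF) / _DEG


def rp_zero_shear_quasistatic(
    flexion_deg: float, anat: AnatomyTable, bounds: SolverBounds = DEFAULT_BOUNDS
) -> tuple[float, str]:
    """Application distance rP* = aF/sinγ nulling the shear quasi-statically.

    Returns ``(rP*, flag)`` with flag in ``{"feasible", "out_of_bounds",
    "always_pcl"}``: where sinγ ≤ 0 no finite distance nulls the shear (rP*
    is ``inf`` and the shear stays PCL-loading for every admissible rP).
    """
    ratios = anat.lever_ratios(flexion_deg)
    rP_star = ratios.aF_over_sin
    if not math.isfinite(rP_star):
        return math.inf, "always_pcl"
    if bounds.rP_min_m <= rP_star <= bounds.rP_max_m:
        return rP_star, "feasible"
    return rP_star, "out_of_bounds"


def commanded_torque(
    tau_opt_nm: float, alpha_deg_s2: float, i_kgm2: float
) -> tuple[float, bool]:
    """Inertial compensation of the prescribed torque: τ_cmd = τ_opt − I·θ̈.

    Lowering the commanded torque during the acceleration phase (θ̈ > 0) and
    raising it during deceleration keeps the muscle force at its quasi-static
    target. Returns ``(τ_cmd, feasible)``; a non-positive τ_cmd would require
    the machine to assist rather than resist and is flagged infeasible.
    """
    tau_cmd = tau_opt_nm - i_kgm2 * alpha_deg_s2 * _DEG
    return tau_cmd, tau_cmd > 0


@dataclass(frozen=True)
class SolveResult:
    """Outcome of a single-point inverse solve."""

    config: ResistanceConfig | None
    reaction: JointReaction | None
    feasible: bool
    violation: str | None = None


def _infeasible(violation: str, strict: bool) -> SolveResult:
    if strict:
        raise InfeasibleConfiguration(violation)
    return SolveResult(config=None, reaction=None, feasible=False, violation=violation)


def solve_configuration(
    state: JointState,
    tau_cmd_nm: float,
    seg: SegmentInertia,
    anat: AnatomyTable,
    shear_target_n: float | None = None,
    axial_target_n: float | None = None,
    tau_phi_nm: float = 0.0,
    bounds: SolverBounds = DEFAULT_BOUNDS,
    rP_default_m: float | None = None,
    strict: bool = True,
) -> SolveResult:
    """Closed-form (R, β, rP) solve under the torque constraint R·rP·cosβ = τ_cmd.

    Solution chain: (i) if a shear target is given, the shear decomposition is
    linear in 1/rP once R·cosβ = τ_cmd/rP is substituted, giving

        1/rP = sinγ/aF + [shear* − (m·rC − I·sinγ/aF)·θ̈ − (sinγ/aF)·τϕ]/τ_cmd;

    otherwise rP is the caller default (distal pad, rP_max). (ii) If an axial
    target is given, the axial decomposition is linear in tanβ at fixed rP:

        tanβ = rP·[axial* + m·rC·θ̇² − (cosγ/aF)·(I·θ̈ − τϕ)]/τ_cmd − rP·cosγ/aF;

    otherwise β = 0. (iii) R = τ_cmd/(rP·cosβ). The returned reaction is
    recomputed through the forward model as verification.

    With ``strict=True`` a binding bound raises
    :class:`InfeasibleConfiguration`; otherwise an infeasible
    :class:`SolveResult` carrying the violated constraint is returned.
    """
    if tau_cmd_nm <= 0:
        return _infeasible(
            f"tau_cmd={tau_cmd_nm:.3g} N*m <= 0 (assistive demand)", strict
        )
    ratios = anat.lever_ratios(state.flexion_deg)
    alpha = state.alpha_rad_s2
    omega = state.omega_rad_s

    # (i) application distance
    if shear_target_n is not None:
        accel_factor = seg.m_kg * seg.r_c_m - seg.i_kgm2 * ratios.sin_over_aF
        inv_rP = (
            ratios.sin_over_aF
            + (shear_target_n - accel_factor * alpha - ratios.sin_over_aF * tau_phi_nm)
            / tau_cmd_nm
        )
        if inv_rP <= 0:
            return _infeasible(
                "rP: shear target unreachable (required 1/rP <= 0; "
                "PCL-loading shear persists for every admissible rP)",
                strict,
            )
        rP = 1.0 / inv_rP
    else:
        rP = rP_default_m if rP_default_m is not None else bounds.rP_max_m
    if not bounds.rP_min_m - 1e-12 <= rP <= bounds.rP_max_m + 1e-12:
        return _infeasible(
            f"rP={rP:.4g} m outside [{bounds.rP_min_m}, {bounds.rP_max_m}] m",
            strict,
        )

    # (ii) direction
    if axial_target_n is not None:
        tan_beta = (
            rP
            * (
                axial_target_n
                + seg.m_kg * seg.r_c_m * omega**2
                - ratios.cos_over_aF * (seg.i_kgm2 * alpha - tau_phi_nm)
            )
            / tau_cmd_nm
            - rP * ratios.cos_over_aF
        )
        beta = math.atan(tan_beta)
    else:
        beta = 0.0
    if abs(beta) >= bounds.beta_limit_deg * _DEG - 1e-12:
        return _infeasible(
            f"beta={beta / _DEG:.4g} deg outside open "
            f"(-{bounds.beta_limit_deg}, {bounds.beta_limit_deg}) deg",
            strict,
        )

    # (iii) magnitude
    R = tau_cmd_nm / (rP * math.cos(beta))
    if R > bounds.R_max_n:
        return _infeasible(f"R={R:.4g} N exceeds R_max={bounds.R_max_n} N", strict)

    config = ResistanceConfig(R_n=R, beta_deg=beta / _DEG, rP_m=rP)
    reaction = reaction_closed_form(state, config, seg, anat, tau_phi_nm)
    return SolveResult(config=config, reaction=reaction, feasible=True)


@dataclass(frozen=True)
class ControlPlan:
    """Per-sample solved resistance configurations over a motion profile."""

    samples: pd.DataFrame
    mode: str

    @property
    def feasible_fraction(self) -> float:
        return float(self.samples["feasible"].mean())

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


def plan_exercise(
    profile: MotionProfile,
    tau_opt: TorqueProfile,
    mode: str,
    seg: SegmentInertia,
    anat: AnatomyTable,
    passive: PassiveTorqueModel | None = None,
    bounds: SolverBounds = DEFAULT_BOUNDS,
    rP_default_m: float | None = None,
) -> ControlPlan:
    """Solve the resistance configuration at every sample of a motion profile.

    Modes: ``plain`` (fixed distal pad, β = 0), ``zero_shear``,
    ``zero_axial``, ``zero_both`` (shear solved for rP first, then axial for
    β, since rP enters the axial equation). Infeasibility is recorded
    per-sample, never raised.
    """
    if mode not in PLAN_MODES:
        raise ValueError(f"mode must be one of {PLAN_MODES}, got {mode!r}")
    shear_target = 0.0 if mode in ("zero_shear", "zero_both") else None
    axial_target = 0.0 if mode in ("zero_axial", "zero_both") else None

    rows = []
    for t, state in zip(profile.t_s, profile.states):
        flex = min(max(state.flexion_deg, 0.0), 120.0)
        tau_phi = passive.tau_phi(flex) if passive is not None else 0.0
        tau_cmd, torque_ok = commanded_torque(
            tau_opt.tau_at(flex), state.alpha_deg_s2, seg.i_kgm2
        )
        clamped_state = JointState(flex, state.omega_deg_s, state.alpha_deg_s2)
        if not torque_ok:
            result = SolveResult(
                None, None, False, f"tau_cmd={tau_cmd:.3g} N*m <= 0 (assistive demand)"
            )
        else:
            result = solve_configuration(
                clamped_state,
                tau_cmd,
                seg,
                anat,
                shear_target_n=shear_target,
                axial_target_n=axial_target,
                tau_phi_nm=tau_phi,
                bounds=bounds,
                rP_default_m=rP_default_m,
                strict=False,
            )
        cfg, reaction = result.config, result.reaction
        rows.append(
            {
                "t_s": t,
                "flexion_deg": state.flexion_deg,
                "R_N": cfg.R_n if cfg else np.nan,
                "beta_deg": cfg.beta_deg if cfg else np.nan,
                "rP_m": cfg.rP_m if cfg else np.nan,
                "tau_cmd_Nm": tau_cmd,
                "shear_N": reaction.shear_n if reaction else np.nan,
                "axial_N": reaction.axial_n if reaction else np.nan,
                "feasible": result.feasible,
                "violation": result.violation or "",
            }
        )
    return ControlPlan(samples=pd.DataFrame(rows), mode=mode)
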