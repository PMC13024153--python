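"""Motion profiles for knee-extension repetitions.

A repetition is described by sampled joint kinematics (θ, θ̇, θ̈). The joint
angle θ follows the convention θ = 90° − flexion, so θ̇ > 0 during extension;
profiles store the flexion angle for readability and expose θ through
:class:`JointState`. Two generators cover the exercise conditions analysed in
the case study: a quasi-static sweep (θ̇ = θ̈ = 0) and an explosive repetition
with a parabolic angular-velocity profile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anatomy import FLEXION_MAX_DEG, FLEXION_MIN_DEG

__all__ = [
    "JointState",
    "MotionProfile",
    "parabolic_profile",
    "quasi_static_profile",
    "validate_profile",
    "DEFAULT_SAMPLE_RATE_HZ",
]

_DEG = math.pi / 180.0

#: Default sampling rate for generated profiles (representative control loop).
DEFAULT_SAMPLE_RATE_HZ = 1000.0


@dataclass(frozen=True)
class JointState:
    """Instantaneous joint kinematics.

    ``omega_deg_s`` and ``alpha_deg_s2`` are the rates of the joint angle
    θ = 90° − flexion, so both are positive while the knee accelerates into
    extension.
    """

    flexion_deg: float
    omega_deg_s: float = 0.0
    alpha_deg_s2: float = 0.0

    @property
    def theta_deg(self) -> float:
        """Joint angle θ (deg); 0 at 90° flexion, 90 at full extension."""
        return 90.0 - self.flexion_deg

    @property
    def omega_rad_s(self) -> float:
        return self.omega_deg_s * _DEG

    @property
    def alpha_rad_s2(self) -> float:
        return self.alpha_deg_s2 * _DEG


@dataclass(frozen=True)
class MotionProfile:
    """Ordered time series of joint states."""

    t_s: tuple[float, ...]
    states: tuple[JointState, ...]

    def __post_init__(self) -> None:
        if len(self.t_s) != len(self.states):
            raise ValueError("t_s and states must have equal length")
        if len(self.t_s) >= 2 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("sample times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def duration_s(self) -> float:
        return self.t_s[-1] - self.t_s[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t_s,
                "flexion_deg": [s.flexion_deg for s in self.states],
                "omega_deg_s": [s.omega_deg_s for s in self.states],
                "alpha_deg_s2": [s.alpha_deg_s2 for s in self.states],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MotionProfile":
        states = tuple(
            JointState(row.flexion_deg, row.omega_deg_s, row.alpha_deg_s2)
            for row in df.itertuples()
        )
        return cls(t_s=tuple(float(t) for t in df["t_s"]), states=states)

    @classmethod
    def from_csv(cls, path) -> "MotionProfile":
        return cls.from_dataframe(pd.read_csv(path))


def _n_default(duration_s: float, n_samples: int | None) -> int:
    if n_samples is None:
        return int(round(duration_s * DEFAULT_SAMPLE_RATE_HZ)) + 1
    return n_samples


def parabolic_profile(
    peak_velocity_deg_s: float,
    duration_s: float,
    start_flexion_deg: float = FLEXION_MAX_DEG,
    n_samples: int | None = None,
) -> MotionProfile:
    """Explosive repetition with a parabolic angular-velocity profile.

    θ̇(t) = v_peak · 4 t (T − t) / T², so the velocity is zero at both ends,
    peaks at mid-repetition, and the acceleration is linear in time with
    extrema ±4·v_peak/T at the endpoints. θ(t) follows by exact integration;
    the total excursion is (2/3)·v_peak·T.

    A warning is emitted when the excursion exceeds the available range of
    motion below the starting flexion angle; the profile itself is not
    clamped (per-sample anatomy queries clamp instead at evaluation time).
    """
    if peak_velocity_deg_s < 0:
        raise ValueError("peak_velocity_deg_s must be >= 0")
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    n = _n_default(duration_s, n_samples)
    if n < 3:
        raise ValueError("n_samples must be >= 3")

    excursion = 2.0 / 3.0 * peak_velocity_deg_s * duration_s
    available = start_flexion_deg - FLEXION_MIN_DEG
    if excursion > available + 1e-9:
        warnings.warn(
            f"profile excursion {excursion:.1f} deg exceeds the {available:.1f} deg "
            "available below the starting flexion angle; anatomy lookups will be "
            "clamped at the range-of-motion bound during evaluation",
            stacklevel=2,
        )

    t = np.linspace(0.0, duration_s, n)
    T = duration_s
    v = peak_velocity_deg_s * 4.0 * t * (T - t) / T**2
    a = peak_velocity_deg_s * 4.0 * (T - 2.0 * t) / T**2
    # exact integral of the parabola: excursion(t) in degrees of extension
    theta_gain = peak_velocity_deg_s * (2.0 * t**2 / T - 4.0 * t**3 / (3.0 * T**2))
    flexion = start_flexion_deg - theta_gain
    states = tuple(
        JointState(float(f), float(w), float(al))
        for f, w, al in zip(flexion, v, a)
    )
    return MotionProfile(t_s=tuple(float(x) for x in t), states=states)


def quasi_static_profile(
    flexion_start_deg: float = FLEXION_MAX_DEG,
    flexion_end_deg: float = FLEXION_MIN_DEG,
    n_samples: int = 121,
    duration_s: float = 1.0,
) -> MotionProfile:
    """Quasi-static sweep of the flexion range with θ̇ = θ̈ = 0 everywhere."""
    lo, hi = sorted((flexion_start_deg, flexion_end_deg))
    if not (FLEXION_MIN_DEG <= lo and hi <= FLEXION_MAX_DEG):
        raise ValueError(
            f"flexion range [{lo}, {hi}] outside "
            f"[{FLEXION_MIN_DEG}, {FLEXION_MAX_DEG}] deg"
        )
    if hi == lo:
        raise ValueError("flexion range must be non-empty")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    t = np.linspace(0.0, duration_s, n_samples)
    flexion = np.linspace(lo, hi, n_samples)
    states = tuple(JointState(float(f), 0.0, 0.0) for f in flexion)
    return MotionProfile(t_s=tuple(float(x) for x in t), states=states)


def validate_profile(profile: MotionProfile, tol: float = 1e-3) -> list[str]:
    """Check finite-difference consistency of a profile; returns violations.

    Central differences of θ (from the flexion column) are compared with the
    stored θ̇, and differences of θ̇ with θ̈, relative to the peak magnitude of
    each channel. A rate channel that is identically zero is the quasi-static
    idealization (sample time is a sweep parameterization, not physical) and
    is skipped. An empty list means the profile is self-consistent.
    """
    if len(profile) < 3:
        raise ValueError("profile needs >= 3 samples for finite differences")
    df = profile.to_dataframe()
    t = df["t_s"].to_numpy()
    theta = 90.0 - df["flexion_deg"].to_numpy()
    omega = df["omega_deg_s"].to_numpy()
    alpha = df["alpha_deg_s2"].to_numpy()

    violations: list[str] = []
    for name, series, rate in (("omega", theta, omega), ("alpha", omega, alpha)):
        if np.all(rate == 0.0):
            continue
        fd = np.gradient(series, t)
        scale = max(np.max(np.abs(rate)), 1.0)
        bad = np.abs(fd[1:-1] - rate[1:-1]) > tol * scale
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0]) + 1
            violations.append(
                f"{name}: finite difference deviates from stored value at "
                f"sample {idx} (t={t[idx]:.4g}s) beyond relative tol {tol}"
            )
    return violations
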