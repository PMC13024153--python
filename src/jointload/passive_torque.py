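"""End-range passive joint moment model.

Capsuloligamentous tissues contribute a passive moment that is negligible
through the mid-range of motion and rises steeply near terminal extension,
opposing further movement. The model is a simple ramp: zero for flexion
angles at or beyond an engagement angle, growing monotonically to a
configurable end magnitude at full extension. The sign is negative (the
moment opposes extension), matching the convention used by the reaction
decomposition. Flexion-side end-range passive torque is not modelled; the
exercise analysis concerns terminal extension.
"""

from __future__ import annotations

from dataclasses import dataclass

from .anatomy import FLEXION_MAX_DEG, FLEXION_MIN_DEG

__all__ = ["PassiveTorqueModel", "DEFAULT_PASSIVE_MODEL"]


@dataclass(frozen=True)
class PassiveTorqueModel:
    """Ramp model of the end-range passive knee moment.

    Parameters
    ----------
    end_magnitude_nm : float
        |τϕ| at terminal extension (N·m); ~10 N·m is a physiologically
        grounded estimate for the knee.
    engage_flexion_deg : float
        Flexion angle below which the passive moment engages.
    ramp : {"linear", "cubic-smooth"}
        Ramp shape between the engagement angle and full extension;
        "cubic-smooth" uses a smoothstep with zero slope at both ends.
    """

    end_magnitude_nm: float = 10.0
    engage_flexion_deg: float = 20.0
    ramp: str = "linear"

    def __post_init__(self) -> None:
        if self.end_magnitude_nm < 0:
            raise ValueError("end_magnitude_nm must be >= 0")
        if not FLEXION_MIN_DEG < self.engage_flexion_deg < FLEXION_MAX_DEG:
            raise ValueError(
                f"engage_flexion_deg must lie in ({FLEXION_MIN_DEG}, "
                f"{FLEXION_MAX_DEG}), got {self.engage_flexion_deg}"
            )
        if self.ramp not in ("linear", "cubic-smooth"):
            raise ValueError(f"unknown ramp {self.ramp!r}")

    def tau_phi(self, flexion_deg: float) -> float:
        """Passive joint moment τϕ (N·m, ≤ 0) at a flexion angle."""
        if not FLEXION_MIN_DEG <= flexion_deg <= FLEXION_MAX_DEG:
            raise ValueError(
                f"flexion angle {flexion_deg} outside "
                f"[{FLEXION_MIN_DEG}, {FLEXION_MAX_DEG}] deg range of motion"
            )
        if flexion_deg >= self.engage_flexion_deg:
            return 0.0
        s = 1.0 - flexion_deg / self.engage_flexion_deg  # 0 at engage, 1 at 0 deg
        if self.ramp == "cubic-smooth":
            s = s * s * (3.0 - 2.0 * s)
        return -self.end_magnitude_nm * s


DEFAULT_PASSIVE_MODEL = PassiveTorqueModel()
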