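"""Extensor-mechanism geometry: patellar-tendon moment arm and traction angle.

The knee-extension model needs two angle-dependent anatomical functions: the
patellar-tendon moment arm aF(θ) about the knee axis and the traction angle
γ(θ) of the tendon force relative to the negative longitudinal tibial axis.
Both are represented as interpolated anchor tables over the flexion range
0–120°. The shipped default is a calibrated reference anatomy: γ runs linearly
from +20° at full extension to −10° at 120° flexion, and four aF anchors are
pinned so that the case-study worked values are reproduced exactly by the
model equations.

Angle convention: the public API takes the knee FLEXION angle in degrees
(0° = full extension). The dynamics equations use the complementary joint
angle θ = 90° − flexion internally, in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy.interpolate import PchipInterpolator

__all__ = [
    "AnatomyTable",
    "LeverRatios",
    "default_table",
    "load_anatomy",
    "FLEXION_MIN_DEG",
    "FLEXION_MAX_DEG",
    "EPS_SIN",
]

FLEXION_MIN_DEG = 0.0
FLEXION_MAX_DEG = 120.0

#: Guard below which sin γ is treated as non-positive (always-PCL regime).
EPS_SIN = 1e-6

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class LeverRatios:
    """Lever ratios of the extensor mechanism at one joint angle.

    ``cos_over_aF`` and ``sin_over_aF`` (1/m) weight the passive and inertial
    torques in the reaction decomposition; ``aF_over_sin`` (m) is the
    resistance application distance that nulls the quadriceps shear
    contribution, reported as ``inf`` wherever sin γ ≤ 0 (no finite distance
    can null it — the always-PCL regime).
    """

    cos_over_aF: float
    sin_over_aF: float
    aF_over_sin: float


@dataclass(frozen=True)
class AnatomyTable:
    """Anchor table for aF(flexion) and γ(flexion) with interpolation.

    Parameters
    ----------
    flexion_deg, aF_m, gamma_deg : sequences
        Anchor values; flexion angles must be strictly increasing and cover
        the full 0–120° range.
    interpolation : {"linear", "monotone-cubic"}
        Interpolation scheme between anchors (monotone cubic = PCHIP).
    """

    flexion_deg: tuple[float, ...]
    aF_m: tuple[float, ...]
    gamma_deg: tuple[float, ...]
    interpolation: str = "linear"
    _aF_interp: object = field(init=False, repr=False, compare=False, default=None)
    _gamma_interp: object = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        flex = np.asarray(self.flexion_deg, dtype=float)
        aF = np.asarray(self.aF_m, dtype=float)
        gamma = np.asarray(self.gamma_deg, dtype=float)
        if not (flex.size == aF.size == gamma.size) or flex.size < 2:
            raise ValueError("anchors need >= 2 rows of equal length")
        if not np.all(np.diff(flex) > 0):
            raise ValueError("flexion anchors must be strictly increasing")
        if flex[0] > FLEXION_MIN_DEG or flex[-1] < FLEXION_MAX_DEG:
            raise ValueError(
                f"anchors must cover [{FLEXION_MIN_DEG}, {FLEXION_MAX_DEG}] deg, "
                f"got [{flex[0]}, {flex[-1]}]"
            )
        if not np.all(aF > 0):
            raise ValueError("aF anchors must be positive")
        if not np.all(np.abs(gamma) < 90):
            raise ValueError("gamma anchors must lie in (-90, 90) deg")
        if self.interpolation == "linear":
            aF_i = lambda x: np.interp(x, flex, aF)  # noqa: E731
            g_i = lambda x: np.interp(x, flex, gamma)  # noqa: E731
        elif self.interpolation == "monotone-cubic":
            aF_i = PchipInterpolator(flex, aF)
            g_i = PchipInterpolator(flex, gamma)
        else:
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        object.__setattr__(self, "_aF_interp", aF_i)
        object.__setattr__(self, "_gamma_interp", g_i)

    @staticmethod
    def _check_range(flexion_deg: float) -> None:
        if not FLEXION_MIN_DEG <= flexion_deg <= FLEXION_MAX_DEG:
            raise ValueError(
                f"flexion angle {flexion_deg} deg outside "
                f"[{FLEXION_MIN_DEG}, {FLEXION_MAX_DEG}] deg range of motion"
            )

    def gamma_at(self, flexion_deg: float) -> float:
        """Interpolated traction angle γ (deg) at a flexion angle."""
        self._check_range(flexion_deg)
        return float(self._gamma_interp(flexion_deg))

    def aF_at(self, flexion_deg: float) -> float:
        """Interpolated patellar-tendon moment arm aF (m) at a flexion angle."""
        self._check_range(flexion_deg)
        return float(self._aF_interp(flexion_deg))

    def lever_ratios(self, flexion_deg: float) -> LeverRatios:
        """cos γ/aF, sin γ/aF and the zero-shear distance aF/sin γ."""
        gamma = self.gamma_at(flexion_deg) * _DEG
        aF = self.aF_at(flexion_deg)
        sin_g = math.sin(gamma)
        return LeverRatios(
            cos_over_aF=math.cos(gamma) / aF,
            sin_over_aF=sin_g / aF,
            aF_over_sin=aF / sin_g if sin_g > EPS_SIN else math.inf,
        )


def _table_from_records(records: Sequence[dict], interpolation: str) -> AnatomyTable:
    rows = sorted(records, key=lambda r: r["flexion_deg"])
    return AnatomyTable(
        flexion_deg=tuple(float(r["flexion_deg"]) for r in rows),
        aF_m=tuple(float(r["aF_m"]) for r in rows),
        gamma_deg=tuple(float(r["gamma_deg"]) for r in rows),
        interpolation=interpolation,
    )


def load_anatomy(path) -> AnatomyTable:
    """Load an anatomy table from a YAML file.

    Expected layout::

        interpolation: linear
        anchors:
          - {flexion_deg: 0.0, aF_m: 0.0470, gamma_deg: 20.0}
          - ...
    """
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "anchors" not in payload:
        raise ValueError(f"anatomy file {path} must contain an 'anchors' list")
    return _table_from_records(
        payload["anchors"], payload.get("interpolation", "linear")
    )


def default_table() -> AnatomyTable:
    """Calibrated reference anatomy shipped with the package."""
    ref = resources.files("jointload.data").joinpath("default_anatomy.yaml")
    with resources.as_file(ref) as path:
        return load_anatomy(path)
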