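"""Run configuration: YAML loading, validation and defaults.

A run configuration bundles everything the planners need — subject
anthropometrics, inertial fractions, the anatomy table path, the passive
torque model and the solver bounds. Unknown keys are rejected and every
validation error names the offending field.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import yaml

from .anatomy import AnatomyTable, default_table, load_anatomy
from .anthropometry import InertialFractions, SubjectSpec
from .passive_torque import PassiveTorqueModel
from .resistance_control import SolverBounds

__all__ = ["RunConfig", "load_config", "ConfigError"]

log = logging.getLogger("jointload")


class ConfigError(ValueError):
    """Configuration file violates the schema; the message names the field."""


_SCHEMA = {
    "subject": {"stature_m", "body_mass_kg"},
    "fractions": {
        "mass_fraction",
        "com_fraction",
        "gyration_fraction_proximal",
        "segment_length_m",
        "reference_length_m",
    },
    "anatomy": None,  # path string
    "passive_torque": {"end_magnitude_nm", "engage_flexion_deg", "ramp"},
    "bounds": {"rP_min_m", "rP_max_m", "R_max_n", "beta_limit_deg"},
    "log_level": None,
}


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration with defaults applied."""

    subject: SubjectSpec = field(
        default_factory=lambda: SubjectSpec(1.75, 75.0)
    )
    fractions: InertialFractions = field(default_factory=InertialFractions)
    anatomy: AnatomyTable = field(default_factory=default_table)
    passive: PassiveTorqueModel = field(default_factory=PassiveTorqueModel)
    bounds: SolverBounds = field(default_factory=SolverBounds)
    anatomy_path: str | None = None
    log_level: str = "INFO"

    def digest(self) -> str:
        """Short stable hash of the configuration, for log provenance."""
        payload = json.dumps(
            {
                "subject": vars(self.subject),
                "fractions": {
                    k: v for k, v in vars(self.fractions).items()
                },
                "anatomy": {
                    "flexion_deg": self.anatomy.flexion_deg,
                    "aF_m": self.anatomy.aF_m,
                    "gamma_deg": self.anatomy.gamma_deg,
                    "interpolation": self.anatomy.interpolation,
                },
                "passive": vars(self.passive),
                "bounds": vars(self.bounds),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _build_section(name: str, cls, payload: dict):
    allowed = _SCHEMA[name]
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigError(
            f"{name}: unknown key(s) {sorted(unknown)}; allowed: {sorted(allowed)}"
        )
    try:
        return cls(**payload)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration, applying defaults.

    An empty file yields the full default configuration. Defaulted sections
    are logged so every run records the provenance of its parameters.
    """
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    if not isinstance(payload, dict):
        raise ConfigError("top level: expected a mapping of config sections")
    unknown = set(payload) - set(_SCHEMA)
    if unknown:
        raise ConfigError(
            f"top level: unknown key(s) {sorted(unknown)}; "
            f"allowed: {sorted(_SCHEMA)}"
        )

    kwargs: dict = {}
    for section, cls in (
        ("subject", SubjectSpec),
        ("fractions", InertialFractions),
        ("passive_torque", PassiveTorqueModel),
        ("bounds", SolverBounds),
    ):
        key = {"passive_torque": "passive"}.get(section, section)
        if section in payload:
            kwargs[key] = _build_section(section, cls, dict(payload[section]))
        else:
            log.debug("config %s: using packaged defaults", section)
    if "anatomy" in payload:
        kwargs["anatomy"] = load_anatomy(payload["anatomy"])
        kwargs["anatomy_path"] = str(payload["anatomy"])
    else:
        log.debug("config anatomy: using calibrated reference table")
    if "log_level" in payload:
        kwargs["log_level"] = str(payload["log_level"])

    cfg = RunConfig(**kwargs)
    log.info("loaded config %s (hash %s)", path, cfg.digest())
    return cfg
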