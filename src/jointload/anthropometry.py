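"""Segment inertial parameters of the moving limb scaled from subject anthropometrics.

The moving limb in a seated knee-extension exercise is the shank+foot system
rotating about the knee axis. Its mass, knee-to-centre-of-mass distance and
moment of inertia about the knee are obtained from total body mass and stature
through literature inertial fractions (Winter/de Leva-style segment tables).
The shipped defaults describe a 1.75 m, 75 kg reference male and reproduce the
worked numbers of the knee-extension case study.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SubjectSpec",
    "InertialFractions",
    "SegmentInertia",
    "segment_inertia",
    "REFERENCE_SUBJECT",
    "DEFAULT_FRACTIONS",
]

#: Stature (m) of the reference subject used to scale the default segment length.
REFERENCE_STATURE_M = 1.75


@dataclass(frozen=True)
class SubjectSpec:
    """Whole-body anthropometrics.

    Parameters
    ----------
    stature_m : float
        Standing height in metres.
    body_mass_kg : float
        Total body mass in kilograms.
    """

    stature_m: float
    body_mass_kg: float

    def __post_init__(self) -> None:
        if not self.stature_m > 0:
            raise ValueError(f"stature_m must be > 0, got {self.stature_m}")
        if not self.body_mass_kg > 0:
            raise ValueError(f"body_mass_kg must be > 0, got {self.body_mass_kg}")


@dataclass(frozen=True)
class InertialFractions:
    """Literature fractions mapping subject anthropometrics to segment inertials.

    ``mass_fraction`` is the shank+foot mass as a fraction of body mass;
    ``com_fraction`` the knee-to-COM distance as a fraction of segment length
    (measured from the proximal joint); ``gyration_fraction_proximal`` the
    radius of gyration about the proximal joint as a fraction of segment
    length. ``segment_length_m`` optionally pins the segment length outright;
    when ``None`` the reference length is scaled proportionally to stature.
    """

    mass_fraction: float = 0.061
    com_fraction: float = 0.606
    gyration_fraction_proximal: float = 0.735
    segment_length_m: float | None = None
    reference_length_m: float = 0.43

    def __post_init__(self) -> None:
        for name in ("mass_fraction", "com_fraction", "gyration_fraction_proximal"):
            value = getattr(self, name)
            if not 0 < value < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if self.segment_length_m is not None and not self.segment_length_m > 0:
            raise ValueError(
                f"segment_length_m must be > 0, got {self.segment_length_m}"
            )
        if not self.reference_length_m > 0:
            raise ValueError(
                f"reference_length_m must be > 0, got {self.reference_length_m}"
            )


@dataclass(frozen=True)
class SegmentInertia:
    """Inertial parameters of the moving limb about the joint axis.

    Attributes
    ----------
    m_kg : float
        Segment mass.
    r_c_m : float
        Distance from the joint centre to the segment centre of mass along the
        longitudinal axis.
    i_kgm2 : float
        Moment of inertia about the joint axis.
    length_m : float
        Segment length (joint centre to distal end).
    """

    m_kg: float
    r_c_m: float
    i_kgm2: float
    length_m: float

    def __post_init__(self) -> None:
        if not self.m_kg > 0:
            raise ValueError(f"m_kg must be > 0, got {self.m_kg}")
        if not 0 < self.r_c_m < self.length_m:
            raise ValueError(
                f"r_c_m must lie in (0, length_m={self.length_m}), got {self.r_c_m}"
            )
        if not self.i_kgm2 > 0:
            raise ValueError(f"i_kgm2 must be > 0, got {self.i_kgm2}")


def segment_inertia(
    subject: SubjectSpec, fractions: InertialFractions | None = None
) -> SegmentInertia:
    """Scale segment inertial parameters from subject stature and mass.

    The segment length is the explicitly supplied value if any, otherwise the
    reference length scaled by ``stature / 1.75 m``. Mass scales linearly with
    body mass; the moment of inertia uses the proximal radius of gyration,
    ``I = m * (k * L)**2``.

    Examples
    --------
    >>> seg = segment_inertia(SubjectSpec(1.75, 75.0))
    >>> round(seg.m_kg, 3), round(seg.i_kgm2, 3)
    (4.575, 0.457)
    """
    if fractions is None:
        fractions = InertialFractions()
    if fractions.segment_length_m is not None:
        length = fractions.segment_length_m
    else:
        length = fractions.reference_length_m * subject.stature_m / REFERENCE_STATURE_M
    m = fractions.mass_fraction * subject.body_mass_kg
    r_c = fractions.com_fraction * length
    i = m * (fractions.gyration_fraction_proximal * length) ** 2
    return SegmentInertia(m_kg=m, r_c_m=r_c, i_kgm2=i, length_m=length)


#: 1.75 m / 75 kg reference male of the knee-extension case study.
REFERENCE_SUBJECT = SubjectSpec(stature_m=1.75, body_mass_kg=75.0)

#: Default shank+foot fractions (Winter-style tables, proximal gyration radius).
DEFAULT_FRACTIONS = InertialFractions()
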