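"""Segment inertial parameters from subject metadata.

Masses are fractions of body mass; moments of inertia come from radii of
gyration scaled by a segment characteristic length (shank length, foot
length, toe length).  The hindfoot table entry is split into equal halves
for the rearfoot and forefoot segments so that the foot-segment masses sum
exactly to the whole-foot mass together with the toes entry.  Segment COM
positions are the geometric average of the segment's marker locations,
evaluated per frame elsewhere in the pipeline; here only the mass and the
COM-centred inertia tensor (segment frame) are assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AnthropometryConfig
from .errors import MetadataError, TableError
from .io_formats import SubjectMeta


@dataclass
class InertialParams:
    """Mass (kg) and COM-centred inertia tensor (kg m^2, segment frame)."""

    segment: str
    mass: float
    inertia: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))

    def __post_init__(self):
        self.inertia = np.asarray(self.inertia, dtype=float)
        if self.mass < 0:
            raise TableError(f"negative mass for segment {self.segment}")
        validate_inertia(self.inertia)


def validate_inertia(I, tol=1e-9):
    """Symmetry, positive semi-definiteness and the triangle inequalities
    on the principal moments (Ixx + Iyy >= Izz etc.)."""
    I = np.asarray(I, dtype=float)
    if I.shape != (3, 3):
        raise TableError("inertia tensor must be 3x3")
    if np.abs(I - I.T).max() > tol * max(np.abs(I).max(), 1e-300):
        raise TableError("inertia tensor is not symmetric")
    w = np.linalg.eigvalsh(0.5 * (I + I.T))
    if w.min() < -tol * max(abs(w.max()), 1e-300):
        raise TableError("inertia tensor is not positive semi-definite")
    a, b, c = np.sort(w)
    if c > a + b + tol * max(c, 1e-300):
        raise TableError("principal moments violate the triangle inequality")


def _diag_inertia(mass, rogs, length):
    k = np.asarray(rogs, dtype=float) * float(length)
    I = np.diag(mass * k ** 2)
    validate_inertia(I)
    return I


def shank_inertia(subject: SubjectMeta, table: AnthropometryConfig) -> InertialParams:
    """Shank mass and inertia from body mass and shank length."""
    if subject.mass <= 0:
        raise MetadataError("body mass must be positive")
    if subject.shank_length <= 0:
        raise MetadataError("shank length must be positive")
    _check_fractions(table)
    mass = table.shank_mass_fraction * subject.mass
    return InertialParams("SHANK", mass,
                          _diag_inertia(mass, table.shank_rog, subject.shank_length))


def _check_fractions(table: AnthropometryConfig):
    for name in ("shank_mass_fraction", "foot_mass_fraction", "hindfoot_mass_fraction"):
        f = getattr(table, name)
        if not 0.0 < f < 1.0:
            raise TableError(f"{name} must lie in (0, 1); got {f}")
    if table.toes_mass_fraction <= 0:
        raise TableError("hindfoot fraction must be below the whole-foot fraction")


def foot_segment_inertia(subject: SubjectMeta, table: AnthropometryConfig) -> dict:
    """Inertial parameters for RF, FF, TOE and the SINGLE-model FOOT.

    The hindfoot entry is split into equal halves (mass and inertia alike)
    between RF and FF; TOE takes the toes entry.  The SINGLE model's one
    foot segment receives the full hindfoot entry, its toes being treated
    only as a point of force application.
    """
    _check_fractions(table)
    hind_mass = table.hindfoot_mass_fraction * subject.mass
    toes_mass = table.toes_mass_fraction * subject.mass
    hind_inertia = _diag_inertia(hind_mass, table.foot_rog, subject.foot_length)
    return {
        "RF": InertialParams("RF", hind_mass / 2.0, hind_inertia / 2.0),
        "FF": InertialParams("FF", hind_mass / 2.0, hind_inertia / 2.0),
        "TOE": InertialParams("TOE", toes_mass,
                              _diag_inertia(toes_mass, table.toe_rog, subject.toe_length)),
        "FOOT": InertialParams("FOOT", hind_mass, hind_inertia),
    }


def segment_com(marker_positions) -> np.ndarray:
    """Geometric average of a segment's marker locations.

    Accepts (n_markers, 3) for one instant or (T, n_markers, 3) for a
    series; averages over the marker axis.
    """
    p = np.asarray(marker_positions, dtype=float)
    if p.ndim == 2:
        return p.mean(axis=0)
    if p.ndim == 3:
        return p.mean(axis=1)
    raise MetadataError("marker positions must be (n, 3) or (T, n, 3)")
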