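"""Pipeline configuration: lab conventions, marker schema, thresholds.

All sign and axis conventions live here, not in the science code.  The
canonical laboratory frame is X anterior (direction of travel), Y vertical
up, Z to the subject's right; the default side is the right foot.  Angle
sign conventions follow the clinical convention dorsiflexion(+) /
plantarflexion(-), inversion(+)/eversion(-), abduction(+)/adduction(-).

Configuration is a plain dataclass tree, loadable from / dumpable to YAML
so alternative marker sets and conventions can be mapped without code
changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ParameterError

#: Canonical marker labels used by the model recipes.
CANONICAL_MARKERS = (
    "CA",    # insertion of the Achilles tendon on the calcaneus
    "M1B",   # base of the first metatarsal
    "M1H",   # first metatarsal head
    "M5B",   # base of the fifth metatarsal
    "M5H",   # fifth metatarsal head
    "NT",    # navicular tuberosity
    "T5",    # distal edge of middle phalanx of the fifth toe
    "HAL",   # distal edge of the proximal phalanx of the hallux
    "MMAL",  # medial malleolus
    "LMAL",  # lateral malleolus
)

#: Default tracking-cluster assignment.  CAM/CAL are extra calcaneus-shell
#: markers and D2 an extra dorsal second-toe marker; shank shell SH1..SH4.
#: All assignable through TrackingConfig.
DEFAULT_TRACKING = {
    "SHANK": ["SH1", "SH2", "SH3", "SH4", "SH5", "SH6", "SH7", "SH8"],
    "RF": ["CA", "RFP1", "RFP2", "RFP3", "RFP4", "RFP5", "RFP6"],
    "FF": ["NT", "M5B", "M1B", "M1H", "M5H", "DM2", "DM4", "M2H"],
    # M1H sits at the MTP centre and M5H on the (hinge) MTP axis, so both
    # are rigid to the toes as well as the forefoot
    "TOE": ["M1H", "M5H", "HAL", "T5", "D2", "HX", "D3"],
    # SINGLE's one foot segment is tracked by three markers distributed
    # along the length of the foot.
    "FOOT": ["CA", "M1H", "M5H"],
}


@dataclass
class LabConfig:
    """Laboratory axis conventions.

    ``up_axis``/``forward_axis`` index into (x, y, z) = (0, 1, 2).
    ``side`` flips frontal/transverse angle signs for the left foot.
    """

    forward_axis: int = 0
    up_axis: int = 1
    lateral_axis: int = 2
    side: str = "right"
    gravity: float = 9.81  # m/s^2, magnitude

    def gravity_vector(self):
        import numpy as np

        g = np.zeros(3)
        g[self.up_axis] = -self.gravity
        return g

    def angle_signs(self):
        """Multipliers converting raw ZXY Cardan angles (about z, x, y) to
        clinical components (dorsiflexion+, inversion+, abduction+)."""
        if self.side == "right":
            return (1.0, 1.0, -1.0)
        if self.side == "left":
            return (1.0, -1.0, 1.0)
        raise ParameterError(f"unknown side {self.side!r}")


@dataclass
class FilterConfig:
    marker_cutoff_hz: float | None = 10.0
    force_cutoff_hz: float | None = 45.0
    order: int = 2  # single-pass order; applied forward and reverse


@dataclass
class StanceConfig:
    threshold_n: float = 20.0
    debounce_s: float = 0.010
    nodes: int = 101


@dataclass
class AssignConfig:
    """GRF segment-assignment options (COP-region technique)."""

    margin_m: float = 0.05       # tolerated COP overshoot along the foot axis
    hysteresis: bool = False     # if True, assignment can only advance distally


@dataclass
class TrackingConfig:
    clusters: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_TRACKING.items()})


@dataclass
class AnthropometryConfig:
    """Mass fractions of body mass and radii of gyration (per segment
    characteristic length).  Defaults are editable, standard-literature
    values -- they are defaults, not measured values; override per subject
    when better data exist.  ``hindfoot`` is split into equal halves for
    the rearfoot and forefoot segments."""

    shank_mass_fraction: float = 0.0465
    shank_rog: tuple = (0.302, 0.302, 0.150)  # about (ml, ap, long) axes / shank length
    foot_mass_fraction: float = 0.0145
    hindfoot_mass_fraction: float = 0.0119    # of body mass; rest of foot = toes
    foot_rog: tuple = (0.475, 0.475, 0.190)   # / foot length
    toe_rog: tuple = (0.30, 0.30, 0.25)       # / toe segment length (short segment)

    @property
    def toes_mass_fraction(self) -> float:
        return self.foot_mass_fraction - self.hindfoot_mass_fraction


@dataclass
class PipelineConfig:
    lab: LabConfig = field(default_factory=LabConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    stance: StanceConfig = field(default_factory=StanceConfig)
    assign: AssignConfig = field(default_factory=AssignConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    anthropometry: AnthropometryConfig = field(default_factory=AnthropometryConfig)
    schema_version: int = 1

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        for section, payload in raw.items():
            if not hasattr(cfg, section):
                raise ParameterError(f"unknown config section {section!r}")
            target = getattr(cfg, section)
            if isinstance(payload, dict) and hasattr(target, "__dataclass_fields__"):
                for key, value in payload.items():
                    if key not in target.__dataclass_fields__:
                        raise ParameterError(f"unknown config key {section}.{key}")
                    if isinstance(value, list) and isinstance(getattr(target, key), tuple):
                        value = tuple(value)
                    setattr(target, key, value)
            else:
                setattr(cfg, section, payload)
        return cfg


DEFAULT_CONFIG = PipelineConfig()
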