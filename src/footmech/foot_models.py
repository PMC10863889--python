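"""SINGLE and MULTI foot model topologies.

The MULTI model splits the foot into rearfoot (RF, calcaneus), forefoot
(FF, navicular through metatarsals) and toes (TOE); the SINGLE model is
one rigid segment from the ankle to the MTP joint, its toes kept only as a
point of force application.  The single-segment foot and the rearfoot
share one anatomical frame recipe so both models use the identical ankle
convention and their ankle kinematics are directly comparable.

Anatomical frames are built once from the neutral standing trial; dynamic
segment orientation comes from a least-squares cluster fit of each
segment's own tracking markers.  That separation is what lets SINGLE and
MULTI share the ankle frame yet report different dynamic angles: SINGLE's
foot cluster spans articulating bones, so midfoot motion folds into its
"foot" pose.

Forefoot frame note: the forefoot transverse axis is the M1H->M5H line;
the frame is completed through the base of the first metatarsal (M1B),
giving a well-conditioned dorsal axis from markers already in the set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .anthropometry import segment_com
from .config import LabConfig, PipelineConfig, DEFAULT_CONFIG
from .errors import (
    DegenerateGeometryError,
    NoContactError,
    ParameterError,
    SchemaError,
)
from .io_formats import ForcePlateRecord, MarkerTrajectorySet, TrialBundle
from .rigid_body import (
    angular_acceleration,
    angular_velocity,
    cardan_zxy_decompose,
    derivative,
    estimate_pose_series,
    relative_joint_rotation,
)

#: Clinical angle components, in storage order.
COMPONENTS = ("sagittal", "frontal", "transverse")  # dorsi+, inversion+, abduction+


# ---------------------------------------------------------------------------
# model definitions

@dataclass
class JointDefinition:
    name: str
    proximal: str
    distal: str
    center_markers: tuple  # one marker -> that point; two -> their midpoint


@dataclass
class SegmentDefinition:
    name: str
    frame_recipe: str          # key into _FRAME_RECIPES
    tracking: list = field(default_factory=list)


@dataclass
class ModelDefinition:
    model_id: str
    segments: list
    joints: list

    def segment(self, name):
        for s in self.segments:
            if s.name == name:
                return s
        raise SchemaError(f"model {self.model_id} has no segment {name!r}")

    def foot_segments(self):
        """Foot-chain segment names, distal to proximal."""
        return [s.name for s in self.segments if s.name != "SHANK"][::-1]


def make_model(model_id: str, config: PipelineConfig | None = None) -> ModelDefinition:
    """Construct the SINGLE or MULTI model with tracking clusters taken
    from the configuration (so alternative marker sets can be assigned
    without code changes)."""
    config = config or DEFAULT_CONFIG
    clusters = config.tracking.clusters
    ankle = JointDefinition("ankle", "SHANK", None, ("MMAL", "LMAL"))
    if model_id.upper() == "MULTI":
        ankle.distal = "RF"
        return ModelDefinition("MULTI", [
            SegmentDefinition("SHANK", "shank", list(clusters["SHANK"])),
            SegmentDefinition("RF", "rearfoot", list(clusters["RF"])),
            SegmentDefinition("FF", "forefoot", list(clusters["FF"])),
            SegmentDefinition("TOE", "toes", list(clusters["TOE"])),
        ], [
            ankle,
            JointDefinition("midtarsal", "RF", "FF", ("NT", "M5B")),
            JointDefinition("mtp", "FF", "TOE", ("M1H",)),
        ])
    if model_id.upper() == "SINGLE":
        ankle.distal = "FOOT"
        return ModelDefinition("SINGLE", [
            SegmentDefinition("SHANK", "shank", list(clusters["SHANK"])),
            # same frame recipe as the rearfoot: identical ankle convention
            SegmentDefinition("FOOT", "rearfoot", list(clusters["FOOT"])),
        ], [ankle])
    raise ParameterError(f"unknown model id {model_id!r}")


# ---------------------------------------------------------------------------
# anatomical frames

def _unit(v, context):
    n = np.linalg.norm(v)
    if n < 1e-10:
        raise DegenerateGeometryError(f"degenerate frame recipe for {context}")
    return v / n


def _cross_unit(a, b, context):
    return _unit(np.cross(a, b), context)


def _sign_up(axis, lab: LabConfig):
    return axis if axis[lab.up_axis] >= 0 else -axis


def _rearfoot_frame(m, lab):
    x = _unit(m["M1H"] - m["CA"], "rearfoot x-axis")
    v = _unit(0.5 * (m["M1H"] + m["M5H"]) - m["CA"], "rearfoot plane")
    y = _sign_up(_cross_unit(x, v, "rearfoot (CA, M1H, M5H collinear?)"), lab)
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def _forefoot_frame(m, lab):
    z = _unit(m["M5H"] - m["M1H"], "forefoot z-axis")
    v = _unit(m["M1H"] - m["M1B"], "forefoot long axis")
    y = _sign_up(_cross_unit(z, v, "forefoot (M1B, M1H, M5H collinear?)"), lab)
    x = np.cross(y, z)
    return np.column_stack([x, y, z])


def _toes_frame(m, lab):
    x = _unit(m["HAL"] - m["M1H"], "toes x-axis")
    v = _unit(m["HAL"] - m["T5"], "toes plane")
    y = _sign_up(_cross_unit(x, v, "toes (M1H, HAL, T5 collinear?)"), lab)
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


def _shank_frame(m, lab, tracking=()):
    ankle = 0.5 * (m["MMAL"] + m["LMAL"])
    cluster = [m[n] for n in tracking if n in m]
    if not cluster:
        raise SchemaError("shank frame needs the shank tracking cluster")
    y = _unit(np.mean(cluster, axis=0) - ankle, "shank long axis")
    malleolar = m["LMAL"] - m["MMAL"]
    if lab.side == "left":
        malleolar = -malleolar
    x = _cross_unit(y, malleolar, "shank (malleoli aligned with long axis?)")
    z = np.cross(x, y)
    return np.column_stack([x, y, z])


_FRAME_RECIPES = {
    "rearfoot": _rearfoot_frame,
    "forefoot": _forefoot_frame,
    "toes": _toes_frame,
    "shank": _shank_frame,
}


def build_anatomical_frames(static: MarkerTrajectorySet, model: ModelDefinition,
                            lab: LabConfig | None = None) -> dict:
    """Anatomical frame of every model segment from the averaged neutral
    standing trial.  Returns {segment name: R (lab <- segment, columns =
    x, y, z axes)}; all frames are orthonormal and right-handed."""
    lab = lab or LabConfig()
    means = static.mean_positions()
    out = {}
    for seg in model.segments:
        recipe = _FRAME_RECIPES[seg.frame_recipe]
        if seg.frame_recipe == "shank":
            R = recipe(means, lab, tracking=seg.tracking)
        else:
            R = recipe(means, lab)
        # guaranteed by construction, cheap to assert
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise DegenerateGeometryError(f"frame for {seg.name} not right-handed")
        out[seg.name] = R
    return out


def joint_centers(markers, model: ModelDefinition) -> dict:
    """Joint-centre positions from marker data.

    ``markers`` may be a mapping {name: (3,) or (T, 3)} or a
    :class:`MarkerTrajectorySet` (then the full series is used).  Ankle =
    malleoli midpoint, midtarsal = NT/M5B midpoint, MTP = M1H.
    """
    if isinstance(markers, MarkerTrajectorySet):
        markers = {n: markers.get(n) for n in markers.names}
    out = {}
    for joint in model.joints:
        pts = []
        for name in joint.center_markers:
            if name not in markers:
                raise SchemaError(f"joint {joint.name} needs marker {name!r}")
            pts.append(np.asarray(markers[name], dtype=float))
        out[joint.name] = pts[0] if len(pts) == 1 else 0.5 * (pts[0] + pts[1])
    return out


# ---------------------------------------------------------------------------
# stance detection and time normalisation

@dataclass
class StanceWindow:
    """First/last contact samples (inclusive) at a given rate."""

    first: int
    last: int
    rate: float

    @property
    def duration(self) -> float:
        return (self.last - self.first) / self.rate

    @property
    def n_samples(self) -> int:
        return self.last - self.first + 1


def detect_stance(forces: ForcePlateRecord, threshold: float = 20.0,
                  debounce_s: float = 0.010) -> StanceWindow:
    """Stance window from the vertical GRF with debounce.

    Contact runs shorter than ``debounce_s`` are ignored.  Raises
    :class:`NoContactError` when the force never crosses the threshold;
    returns the full record with a warning when it never drops below.
    """
    fz = forces.vertical_force
    above = fz >= threshold
    if not above.any():
        raise NoContactError(f"vertical force never reaches {threshold} N")
    if above.all():
        warnings.warn("vertical force above threshold throughout the record; "
                      "using the full record as stance")
        return StanceWindow(0, len(fz) - 1, forces.rate)
    min_run = max(1, int(round(debounce_s * forces.rate)))
    edges = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]))
    starts, stops = edges[::2], edges[1::2]  # [start, stop) pairs
    keep = (stops - starts) >= min_run
    if not keep.any():
        raise NoContactError("no contact interval survives the debounce")
    return StanceWindow(int(starts[keep][0]), int(stops[keep][-1] - 1), forces.rate)


def time_normalize(series, window: StanceWindow, nodes: int = 101) -> np.ndarray:
    """Linear interpolation of a uniform series onto ``nodes`` points
    equally spaced over 0..100% of the stance window."""
    series = np.asarray(series, dtype=float)
    if window.first < 0 or window.last >= len(series):
        raise ParameterError("stance window lies outside the record")
    xi = np.linspace(window.first, window.last, nodes)
    x = np.arange(len(series))
    if series.ndim == 1:
        return np.interp(xi, x, series)
    flat = series.reshape(len(series), -1)
    out = np.stack([np.interp(xi, x, flat[:, j]) for j in range(flat.shape[1])], axis=1)
    return out.reshape((nodes,) + series.shape[1:])


def excursion(series) -> float:
    """Total excursion (max minus min) of an angle component over stance."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ParameterError("excursion needs at least 2 samples")
    return float(series.max() - series.min())


# ---------------------------------------------------------------------------
# per-trial kinematics

@dataclass
class SegmentKinematics:
    """Tracked motion of one segment over the dynamic trial (full record,
    marker rate, lab frame)."""

    name: str
    R_track: np.ndarray   # (T,3,3) rotation from static configuration
    R_anat: np.ndarray    # (T,3,3) anatomical frame orientation
    omega: np.ndarray     # (T,3) rad/s
    alpha: np.ndarray     # (T,3) rad/s^2
    com: np.ndarray       # (T,3) m
    com_acc: np.ndarray   # (T,3) m/s^2


@dataclass
class TrialKinematics:
    model: ModelDefinition
    rate: float
    anat_frames: dict          # static anatomical frames
    segments: dict             # name -> SegmentKinematics
    joint_centers: dict        # joint -> (T,3)
    stance: StanceWindow
    forces: ForcePlateRecord   # filtered, resampled to marker rate
    markers: MarkerTrajectorySet  # filtered dynamic markers


@dataclass
class JointAngleSeries:
    """Stance-normalised joint angles and angular velocities.

    ``angles`` (nodes, 3) degrees and ``omega`` (nodes, 3) deg/s in the
    clinical component order ``COMPONENTS`` = (sagittal dorsiflexion+,
    frontal inversion+, transverse abduction+).  ``omega_frame`` tags the
    frame of the velocity components (proximal anatomical frame).
    """

    joint: str
    angles: np.ndarray
    omega: np.ndarray
    nodes: int = 101
    omega_frame: str = "proximal_anatomical"

    def component(self, name: str) -> np.ndarray:
        return self.angles[:, COMPONENTS.index(name)]


def compute_trial_kinematics(bundle: TrialBundle, model: ModelDefinition,
                             config: PipelineConfig | None = None) -> TrialKinematics:
    """Filter, fit cluster poses, differentiate, and window one trial."""
    from .io_formats import resample_to_marker_rate

    config = config or DEFAULT_CONFIG
    lab = config.lab
    mc = config.filters.marker_cutoff_hz
    dyn = bundle.dynamic.filtered(mc, config.filters.order) if mc else bundle.dynamic
    if bundle.dynamic.gaps.any():
        raise SchemaError("dynamic trial contains marker gaps; gap-filling "
                          "is deliberately not performed")
    A = build_anatomical_frames(bundle.static, model, lab)
    static_means = bundle.static.mean_positions()
    segments = {}
    for seg in model.segments:
        ref = np.stack([static_means[n] for n in seg.tracking])
        obs = dyn.subset(seg.tracking)
        R_track, _ = estimate_pose_series(ref, obs)
        R_anat = R_track @ A[seg.name]
        omega = angular_velocity(R_anat, dyn.rate)
        alpha = angular_acceleration(omega, dyn.rate)
        com = segment_com(obs)
        com_acc = derivative(com, dyn.rate, order=2)
        segments[seg.name] = SegmentKinematics(seg.name, R_track, R_anat,
                                               omega, alpha, com, com_acc)
    fc = config.filters.force_cutoff_hz
    forces = bundle.forces
    if fc:
        from .rigid_body import butter_zero_lag
        forces = ForcePlateRecord(
            forces.rate,
            butter_zero_lag(forces.force, fc, forces.rate, axis=0),
            forces.cop, forces.free_moment,
            contact_threshold=forces.contact_threshold, lab=forces.lab)
    forces = resample_to_marker_rate(forces, dyn.rate)
    if forces.n_samples < dyn.n_frames:
        raise ParameterError("force record shorter than the marker record")
    stance = detect_stance(forces, config.stance.threshold_n, config.stance.debounce_s)
    if stance.last >= dyn.n_frames:
        stance = StanceWindow(stance.first, dyn.n_frames - 1, stance.rate)
    centers = joint_centers(dyn, model)
    return TrialKinematics(model, dyn.rate, A, segments, centers, stance,
                           forces, dyn)


def compute_joint_angles(kin_or_bundle, model: ModelDefinition | None = None,
                         config: PipelineConfig | None = None) -> dict:
    """Stance-normalised Cardan angles and angular velocities per joint.

    Accepts a :class:`TrialBundle` (with ``model``) or a pre-computed
    :class:`TrialKinematics`.  For each joint the relative rotation of the
    distal anatomical frame with respect to the proximal one is offset by
    the neutral standing pose, decomposed with the ZXY sequence, mapped to
    clinical signs, windowed to stance and normalised to 101 nodes.
    """
    config = config or DEFAULT_CONFIG
    if isinstance(kin_or_bundle, TrialBundle):
        kin = compute_trial_kinematics(kin_or_bundle, model, config)
    else:
        kin = kin_or_bundle
    model = kin.model
    signs = np.asarray(config.lab.angle_signs())
    nodes = config.stance.nodes
    out = {}
    for joint in model.joints:
        prox = kin.segments[joint.proximal]
        dist = kin.segments[joint.distal]
        R_rel = relative_joint_rotation(prox.R_anat, dist.R_anat,
                                        kin.anat_frames[joint.proximal],
                                        kin.anat_frames[joint.distal])
        raw = cardan_zxy_decompose(R_rel)  # (T,3): about z, x, y
        angles = raw * signs
        w_lab = dist.omega - prox.omega
        w_prox = np.einsum("tji,tj->ti", prox.R_anat, w_lab)  # into prox frame
        # reorder (x,y,z) components to (sagittal z, frontal x, transverse y)
        w_cl = np.stack([w_prox[:, 2], w_prox[:, 0], w_prox[:, 1]], axis=1)
        w_cl = np.rad2deg(w_cl) * signs
        out[joint.name] = JointAngleSeries(
            joint.name,
            time_normalize(angles, kin.stance, nodes),
            time_normalize(w_cl, kin.stance, nodes),
            nodes=nodes)
    return out
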