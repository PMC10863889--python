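"""Inverse dynamics of the foot chain.

The measured GRF is assigned, sample by sample, to exactly one foot
segment: the one whose boundary along the foot's longitudinal axis
(delimited by the proximal and distal joint centres) contains the centre
of pressure.  Resultant joint forces and moments are then obtained by a
recursive Newton-Euler pass from the toes inward (TOE -> FF -> RF for the
three-segment model; the single-segment model solves only the ankle, with
the whole GRF acting on its one foot segment).  All equations are
evaluated in the lab frame with the inertia tensor rotated per sample.

Joint moments are reported as the couple acting on the distal segment at
the joint.  Instantaneous joint power is the scalar product of that
moment with the relative angular velocity of the distal segment with
respect to the proximal one (lab frame; the scalar product is frame
invariant when both factors share a frame).  Work is the time integral of
power, split into positive, negative and net parts.

:func:`free_body_joint_loads` computes the same joint loads by direct
summation over every segment distal to the joint -- no recursion -- and
serves as an independent cross-check of the recursive implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .errors import AlignmentError, ParameterError
from .foot_models import ModelDefinition, TrialKinematics

__all__ = [
    "LoadAssignmentSeries", "JointKinetics", "WorkSummary",
    "assign_grf", "assign_grf_series", "newton_euler",
    "free_body_joint_loads", "joint_power", "joint_work",
    "normalize_by_mass", "compute_joint_kinetics",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class LoadAssignmentSeries:
    """Per-sample segment receiving the entire GRF, COP and free moment."""

    segments: np.ndarray          # (T,) of segment-name strings ('' = no load)
    s_cop: np.ndarray = None      # COP coordinate along the foot axis (m)

    def counts(self):
        names, counts = np.unique(self.segments[self.segments != ""], return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))


@dataclass
class JointKinetics:
    """Resultant force, moment and power at one joint over stance."""

    joint: str
    rate: float
    force: np.ndarray       # (T,3) N  (or N/kg when normalized)
    moment: np.ndarray      # (T,3) N*m (or N*m/kg)
    power: np.ndarray = None  # (T,) W (or W/kg)
    normalized: bool = False


@dataclass
class WorkSummary:
    joint: str
    positive: float
    negative: float
    net: float
    normalized: bool = False


# ---------------------------------------------------------------------------
# GRF assignment

def _horizontal_unit(v, up_axis):
    v = np.array(v, dtype=float)
    v[up_axis] = 0.0
    n = np.linalg.norm(v)
    if n == 0:
        raise ParameterError("foot axis has no horizontal component")
    return v / n


def assign_grf(cop, centers, foot_axis, extent=None, up_axis=1):
    """Assign one COP sample to RF, FF or TOE.

    ``centers`` maps 'midtarsal' and 'mtp' to their 3-D positions; all
    points are projected onto the horizontal projection of ``foot_axis``
    (the rearfoot longitudinal axis).  A COP proximal to the midtarsal
    centre loads the rearfoot, between midtarsal and MTP the forefoot,
    and at or beyond the MTP centre the toes (boundary samples assign
    distally).  ``extent=(s_min, s_max)`` bounds along the same axis
    trigger a clamping warning when exceeded.
    """
    axis = _horizontal_unit(foot_axis, up_axis)
    s = float(np.dot(cop, axis))
    s_mt = float(np.dot(centers["midtarsal"], axis))
    s_mtp = float(np.dot(centers["mtp"], axis))
    if extent is not None and not (extent[0] <= s <= extent[1]):
        warnings.warn("COP outside the foot's longitudinal extent; clamped")
        s = min(max(s, extent[0]), extent[1])
    if s < s_mt:
        return "RF"
    if s < s_mtp:
        return "FF"
    return "TOE"


def assign_grf_series(kin: TrialKinematics, config: PipelineConfig | None = None
                      ) -> LoadAssignmentSeries:
    """Vectorised COP-region assignment over the stance window.

    For the SINGLE model every loaded sample is assigned to the one FOOT
    segment.  With ``config.assign.hysteresis`` the assignment may only
    advance distally (RF -> FF -> TOE), suppressing boundary chatter.
    """
    config = config or DEFAULT_CONFIG
    model = kin.model
    up = config.lab.up_axis
    T = kin.forces.n_samples
    seg = np.full(T, "", dtype=object)
    loaded = kin.forces.contact_mask & np.isfinite(kin.forces.cop[:, 0])
    s_cop = np.full(T, np.nan)
    if model.model_id == "SINGLE":
        seg[loaded] = "FOOT"
        return LoadAssignmentSeries(np.asarray(seg, dtype=object), s_cop)

    foot = kin.segments["RF"]
    axes = foot.R_anat[:, :, 0].copy()    # rearfoot x-axis per sample
    axes[:, up] = 0.0
    norms = np.linalg.norm(axes, axis=1, keepdims=True)
    axes = axes / np.where(norms == 0, 1.0, norms)
    n = min(T, len(axes))

    def proj(p):
        return np.einsum("ti,ti->t", p[:n], axes[:n])

    s_mt = proj(kin.joint_centers["midtarsal"])
    s_mtp = proj(kin.joint_centers["mtp"])
    cop = np.nan_to_num(kin.forces.cop[:n], nan=0.0)
    s = np.einsum("ti,ti->t", cop, axes[:n])
    s_cop[:n] = s
    heel = proj(kin.markers.get("CA"))
    hal = proj(kin.markers.get("HAL"))
    margin = config.assign.margin_m
    lo, hi = heel - margin, hal + margin
    m = loaded[:n]
    if (s[m] < lo[m]).any() or (s[m] > hi[m]).any():
        warnings.warn("COP outside the foot's longitudinal extent; clamped")
        s = np.clip(s, lo, hi)
    ids = np.where(s < s_mt, "RF", np.where(s < s_mtp, "FF", "TOE"))
    if config.assign.hysteresis:
        order = {"RF": 0, "FF": 1, "TOE": 2}
        best = 0
        for i in np.flatnonzero(m):
            best = max(best, order[ids[i]])
            ids[i] = ("RF", "FF", "TOE")[best]
    seg[:n][m] = ids[m]
    return LoadAssignmentSeries(np.asarray(seg, dtype=object), s_cop)


# ---------------------------------------------------------------------------
# Newton-Euler recursion

def _external_loads(names, assignment, forces, up_axis):
    """Per-segment external force / COP / free moment arrays."""
    T = forces.n_samples
    out = {}
    for name in names:
        sel = assignment.segments == name
        F = np.zeros((T, 3))
        cop = np.zeros((T, 3))
        Mfree = np.zeros((T, 3))
        F[sel] = forces.force[sel]
        cop[sel] = np.nan_to_num(forces.cop[sel], nan=0.0)
        Mfree[sel, up_axis] = forces.free_moment[sel]
        out[name] = (F, cop, Mfree)
    return out


def newton_euler(chain, joints, kinematics, inertial, assignment, forces,
                 joint_centers, gravity=(0.0, -9.81, 0.0), up_axis=1):
    """Recursive Newton-Euler pass over a distal-to-proximal segment chain.

    Parameters
    ----------
    chain : list of segment names, distal first (e.g. ['TOE','FF','RF']).
    joints : list of joint names, ``joints[i]`` being the proximal joint
        of ``chain[i]`` (e.g. ['mtp','midtarsal','ankle']).
    kinematics : {segment: object} with per-sample ``R_anat`` (T,3,3),
        ``omega``/``alpha`` (T,3) and ``com``/``com_acc`` (T,3).
    inertial : {segment: InertialParams}.
    assignment : LoadAssignmentSeries; forces : ForcePlateRecord at the
        same rate and length; joint_centers : {joint: (T,3)}.

    Returns {joint: JointKinetics} (power left unset here).
    """
    g = np.asarray(gravity, dtype=float)
    T = forces.n_samples
    for name in chain:
        k = kinematics[name]
        if len(k.com) != T or len(k.omega) != T:
            raise AlignmentError("kinematic series length does not match forces")
    ext = _external_loads(chain, assignment, forces, up_axis)
    out = {}
    F_d = np.zeros((T, 3))   # reaction from the previously solved distal joint
    M_d = np.zeros((T, 3))
    r_d_point = None         # its application point
    for name, joint in zip(chain, joints):
        k = kinematics[name]
        p = inertial[name]
        m = p.mass
        R = k.R_anat
        I_lab = np.einsum("tij,jk,tlk->til", R, p.inertia, R)
        F_ext, cop, M_free = ext[name]
        F_p = m * k.com_acc - m * g[None, :] - F_ext - F_d
        Iw = np.einsum("tij,tj->ti", I_lab, k.omega)
        gyro = np.cross(k.omega, Iw)
        Ia = np.einsum("tij,tj->ti", I_lab, k.alpha)
        M_p = Ia + gyro - M_d
        if r_d_point is not None:
            M_p -= np.cross(r_d_point - k.com, F_d)
        M_p -= np.cross(cop - k.com, F_ext) + M_free
        r_p = joint_centers[joint][:T] - k.com
        M_p -= np.cross(r_p, F_p)
        out[joint] = JointKinetics(joint, forces.rate, F_p, M_p)
        # reaction passed to the next (more proximal) segment
        F_d = -F_p
        M_d = -M_p
        r_d_point = joint_centers[joint][:T]
    return out


def free_body_joint_loads(joint, chain, joints, kinematics, inertial,
                          assignment, forces, joint_centers,
                          gravity=(0.0, -9.81, 0.0), up_axis=1):
    """Joint force and moment by direct free-body summation.

    Sums m*a - m*g - F_ext over every segment distal to (and including the
    distal side of) ``joint``, and takes moments of all inertial, gravity
    and external terms about the joint centre -- no recursion, no reaction
    bookkeeping.  Independent cross-check for :func:`newton_euler`.
    """
    g = np.asarray(gravity, dtype=float)
    T = forces.n_samples
    idx = joints.index(joint)
    distal = chain[:idx + 1]
    ext = _external_loads(distal, assignment, forces, up_axis)
    pj = joint_centers[joint][:T]
    F = np.zeros((T, 3))
    M = np.zeros((T, 3))
    for name in distal:
        k = kinematics[name]
        p = inertial[name]
        m = p.mass
        R = k.R_anat
        I_lab = np.einsum("tij,jk,tlk->til", R, p.inertia, R)
        F_ext, cop, M_free = ext[name]
        F += m * k.com_acc - m * g[None, :] - F_ext
        Iw = np.einsum("tij,tj->ti", I_lab, k.omega)
        M += (np.einsum("tij,tj->ti", I_lab, k.alpha) + np.cross(k.omega, Iw)
              + np.cross(k.com - pj, m * (k.com_acc - g[None, :]))
              - np.cross(cop - pj, F_ext) - M_free)
    return F, M


# ---------------------------------------------------------------------------
# power and work

def joint_power(moment, rel_omega):
    """Instantaneous power: element-wise scalar product moment . omega."""
    moment = np.asarray(moment, dtype=float)
    rel_omega = np.asarray(rel_omega, dtype=float)
    if moment.shape != rel_omega.shape:
        raise AlignmentError("moment and angular velocity shapes differ")
    return np.einsum("...i,...i->...", moment, rel_omega)


def joint_work(power, dt, joint="", normalized=False) -> WorkSummary:
    """Trapezoidal integration of positive, negative and net power."""
    power = np.asarray(power, dtype=float)
    pos = float(np.trapezoid(np.maximum(power, 0.0), dx=dt))
    neg = float(np.trapezoid(np.minimum(power, 0.0), dx=dt))
    net = float(np.trapezoid(power, dx=dt))
    return WorkSummary(joint, pos, neg, net, normalized=normalized)


def normalize_by_mass(obj, mass):
    """Divide kinetics or work by body mass; refuses to normalise twice."""
    if mass <= 0:
        raise ParameterError("mass must be positive")
    if getattr(obj, "normalized", False):
        raise ParameterError("already normalized")
    if isinstance(obj, JointKinetics):
        return JointKinetics(obj.joint, obj.rate, obj.force / mass,
                             obj.moment / mass,
                             None if obj.power is None else obj.power / mass,
                             normalized=True)
    if isinstance(obj, WorkSummary):
        return WorkSummary(obj.joint, obj.positive / mass, obj.negative / mass,
                           obj.net / mass, normalized=True)
    raise ParameterError(f"cannot normalise {type(obj).__name__}")


# ---------------------------------------------------------------------------
# high-level per-trial kinetics

def _window(arr, w):
    return arr[w.first:w.last + 1]


def compute_joint_kinetics(kin: TrialKinematics, inertial, mass,
                           config: PipelineConfig | None = None):
    """Full stance-phase kinetics of one trial.

    Runs GRF assignment, the Newton-Euler recursion over the stance
    window, joint power (moment . relative angular velocity, lab frame)
    and work integration.  Returns ``(kinetics, works, assignment)`` with
    mass-normalised values (N/kg, N*m/kg, W/kg, J/kg).
    """
    from .io_formats import ForcePlateRecord

    config = config or DEFAULT_CONFIG
    model = kin.model
    w = kin.stance
    assignment = assign_grf_series(kin, config)
    chain = model.foot_segments()
    joints = []
    for seg_name in chain:
        for j in model.joints:
            if j.distal == seg_name:
                joints.append(j.name)
    forces_w = ForcePlateRecord(
        kin.forces.rate, _window(kin.forces.force, w), _window(kin.forces.cop, w),
        _window(kin.forces.free_moment, w),
        contact_threshold=kin.forces.contact_threshold, lab=kin.forces.lab)
    assign_w = LoadAssignmentSeries(assignment.segments[w.first:w.last + 1],
                                    assignment.s_cop[w.first:w.last + 1])

    class _K:  # windowed view of SegmentKinematics
        def __init__(self, k):
            self.R_anat = _window(k.R_anat, w)
            self.omega = _window(k.omega, w)
            self.alpha = _window(k.alpha, w)
            self.com = _window(k.com, w)
            self.com_acc = _window(k.com_acc, w)

    kw = {name: _K(k) for name, k in kin.segments.items()}
    centers_w = {name: _window(c, w) for name, c in kin.joint_centers.items()}
    gravity = config.lab.gravity_vector()
    kinetics = newton_euler(chain, joints, kw, inertial, assign_w, forces_w,
                            centers_w, gravity=gravity, up_axis=config.lab.up_axis)
    prox_of = {j.name: j.proximal for j in model.joints}
    dist_of = {j.name: j.distal for j in model.joints}
    works = {}
    for jname, jk in kinetics.items():
        w_rel = kw[dist_of[jname]].omega - kw[prox_of[jname]].omega
        jk.power = joint_power(jk.moment, w_rel)
    for jname, jk in kinetics.items():
        kinetics[jname] = normalize_by_mass(jk, mass)
        works[jname] = joint_work(kinetics[jname].power, 1.0 / kin.rate,
                                  joint=jname, normalized=True)
    return kinetics, works, assignment
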