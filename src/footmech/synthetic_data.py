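"""Synthetic running-stance trials with known ground truth.

The generator emulates the study protocol the pipeline targets: barefoot
heel-strike running at ~3.1 m/s, markers sampled at 150 Hz, a single force
plate at 1500 Hz, a neutral-standing calibration trial, and a stance phase
of about 0.24 s.  A neutral foot geometry (right foot, metres, lab frame X
anterior / Y up / Z right) carries the full marker set; the dynamic trial
is produced by forward kinematics -- a prescribed shank pose, then
rearfoot, forefoot and toe poses obtained by rotating each segment about
its proximal joint centre by prescribed joint-angle profiles.  Markers
ride rigidly on their segments; optional isotropic Gaussian noise is added
last, after the ground truth has been recorded.

Joint-angle profiles are sums of smooth basis bumps (raised cosines) with
closed-form derivatives, parameterised by amplitude (deg, clinical signs:
dorsiflexion+, inversion+, abduction+), centre and width in % stance.
Profile widths of the shipped defaults are >= 1.25x stance so their
frequency content sits well below the pipeline's 10 Hz marker cutoff.

The GRF is a synthetic double-peak vertical profile (impact + active peak)
with sinusoidal shear and a COP translating monotonically from heel to
toe between the instantaneous heel and hallux marker positions -- the COP
therefore always stays within the foot's longitudinal extent.  The full
3-D running trial is kinematically prescribed but NOT dynamically
consistent; dynamic consistency (for verifying the Newton-Euler
recursion) is provided by the separate planar case in
:mod:`footmech.planar`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import PipelineConfig, DEFAULT_CONFIG
from .errors import SpecError
from .foot_models import (
    MarkerTrajectorySet,
    StanceWindow,
    build_anatomical_frames,
    joint_centers,
    make_model,
)
from .io_formats import ForcePlateRecord, SubjectMeta, TrialBundle
from .rigid_body import cardan_zxy_compose

#: Neutral-standing marker geometry (m): right foot, heel at x ~ 0.
DEFAULT_GEOMETRY = {
    # shank (malleoli + 6-marker shaft shell)
    "MMAL": (0.060, 0.080, -0.035), "LMAL": (0.060, 0.078, 0.040),
    "SH1": (0.075, 0.180, -0.045), "SH2": (0.070, 0.200, 0.045),
    "SH3": (0.055, 0.300, -0.040), "SH4": (0.050, 0.320, 0.042),
    "SH5": (0.080, 0.150, 0.000), "SH6": (0.045, 0.350, 0.000),
    "SH7": (0.012, 0.260, -0.050), "SH8": (0.010, 0.280, 0.048),
    # rearfoot: posterior calcaneus plus a heel cluster reaching up the
    # Achilles insertion, down the medial/lateral walls and forward to
    # the sustentaculum-tali / peroneal-tubercle areas (anterior depth
    # conditions the pose fit)
    "CA": (0.000, 0.055, 0.002),
    "RFP1": (-0.008, 0.088, -0.018), "RFP2": (-0.008, 0.084, 0.022),
    "RFP3": (0.046, 0.018, -0.046), "RFP4": (0.052, 0.024, 0.046),
    "RFP5": (0.018, 0.015, -0.036), "RFP6": (0.022, 0.017, 0.036),
    # forefoot (dorsal markers DM2/DM4 add height spread; M2H rides the
    # metatarsals, not the toes)
    "NT": (0.085, 0.035, -0.022), "M5B": (0.100, 0.022, 0.042),
    "M1B": (0.105, 0.032, -0.028), "M1H": (0.160, 0.028, -0.032),
    "M5H": (0.150, 0.022, 0.048), "DM2": (0.118, 0.048, -0.002),
    "DM4": (0.112, 0.040, 0.026), "M2H": (0.165, 0.030, -0.008),
    # toes (D2 dorsal second toe, D3 dorsal third toe, HX hallux tip)
    "HAL": (0.215, 0.022, -0.028), "T5": (0.185, 0.015, 0.050),
    "D2": (0.205, 0.045, 0.000), "HX": (0.238, 0.016, -0.018),
    "D3": (0.215, 0.030, 0.030),
}

#: Which segment each marker rides on during forward kinematics.
MARKER_SEGMENTS = {
    "MMAL": "SHANK", "LMAL": "SHANK", "SH1": "SHANK", "SH2": "SHANK",
    "SH3": "SHANK", "SH4": "SHANK", "SH5": "SHANK", "SH6": "SHANK",
    "SH7": "SHANK", "SH8": "SHANK",
    "CA": "RF", "RFP1": "RF", "RFP2": "RF", "RFP3": "RF", "RFP4": "RF",
    "RFP5": "RF", "RFP6": "RF",
    "NT": "FF", "M5B": "FF", "M1B": "FF", "M1H": "FF", "M5H": "FF",
    "DM2": "FF", "DM4": "FF", "M2H": "FF",
    "HAL": "TOE", "T5": "TOE", "D2": "TOE", "HX": "TOE", "D3": "TOE",
}


# ---------------------------------------------------------------------------
# smooth profile basis

@dataclass(frozen=True)
class Bump:
    """Raised-cosine bump over stance fraction s in [center +/- width/2]."""

    amplitude_deg: float
    center: float   # fraction of stance
    width: float    # fraction of stance

    def value(self, s):
        s = np.asarray(s, dtype=float)
        u = (s - self.center) / self.width + 0.5
        inside = (u >= 0.0) & (u <= 1.0)
        return np.where(inside,
                        0.5 * self.amplitude_deg * (1.0 - np.cos(2 * np.pi * u)),
                        0.0)

    def deriv(self, s):
        """d/ds, in degrees per unit stance fraction."""
        s = np.asarray(s, dtype=float)
        u = (s - self.center) / self.width + 0.5
        inside = (u >= 0.0) & (u <= 1.0)
        return np.where(inside,
                        self.amplitude_deg * np.pi / self.width
                        * np.sin(2 * np.pi * u),
                        0.0)


@dataclass(frozen=True)
class JointProfile:
    """Per-component bump lists, clinical order (sagittal, frontal, transverse)."""

    sagittal: tuple = ()
    frontal: tuple = ()
    transverse: tuple = ()

    def components(self):
        return (self.sagittal, self.frontal, self.transverse)

    def angles(self, s):
        s = np.asarray(s, dtype=float)
        out = np.zeros(s.shape + (3,))
        for k, bumps in enumerate(self.components()):
            for b in bumps:
                out[..., k] += b.value(s)
        return out

    def rates(self, s):
        s = np.asarray(s, dtype=float)
        out = np.zeros(s.shape + (3,))
        for k, bumps in enumerate(self.components()):
            for b in bumps:
                out[..., k] += b.deriv(s)
        return out

    def scaled(self, factor):
        return JointProfile(*[tuple(replace(b, amplitude_deg=b.amplitude_deg * factor)
                                    for b in bumps)
                              for bumps in self.components()])

    def max_amplitude(self):
        amps = [abs(b.amplitude_deg) for bumps in self.components() for b in bumps]
        return max(amps, default=0.0)


def default_profiles() -> dict:
    """The shipped default joint-angle profiles (heel-strike running).

    Ankle: dorsiflexion through midstance, plantarflexion through
    push-off, small eversion and adduction.  Midfoot: modest dorsiflexion
    (arch compression) at midstance, plantarflexion (arch recoil) late.
    MTP: extension during push-off.
    """
    return {
        "ankle": JointProfile(
            sagittal=(Bump(17.0, 0.40, 1.50), Bump(-23.0, 1.10, 1.50)),
            frontal=(Bump(-6.0, 0.40, 1.30),),
            transverse=(Bump(-5.0, 0.55, 1.30),),
        ),
        "midtarsal": JointProfile(
            sagittal=(Bump(6.0, 0.45, 1.30), Bump(-12.0, 1.10, 1.30)),
            frontal=(Bump(3.0, 0.50, 1.30),),
            transverse=(Bump(-2.5, 0.55, 1.30),),
        ),
        # the MTP behaves as a dorsiflexion hinge: its axis is the
        # M1H -> M5H line, and non-sagittal toe motion is negligible
        "mtp": JointProfile(
            sagittal=(Bump(15.0, 1.00, 1.30),),
        ),
    }


# ---------------------------------------------------------------------------
# trial specification

@dataclass
class SyntheticTrialSpec:
    """Everything the generator needs; the defaults are the emulated study
    conditions (150 / 1500 Hz, ~0.24 s heel-strike stance at 3.1 m/s)."""

    mass: float = 70.0
    geometry: dict = field(default_factory=lambda: dict(DEFAULT_GEOMETRY))
    profiles: dict = field(default_factory=default_profiles)
    shank_angle_deg: tuple = (-14.0, 24.0)   # sagittal shank lean at 0 / 100% stance
    ankle_travel_m: tuple = (0.05, -0.008)   # forward travel, vertical dip
    marker_rate: float = 150.0
    force_rate: float = 1500.0
    stance_duration: float = 0.24
    lead: float = 0.14       # seconds of record before foot contact
    tail: float = 0.14
    static_duration: float = 1.0
    noise_sigma: float = 0.0005  # m, isotropic marker noise
    grf_active_bw: float = 2.3   # active peak, bodyweights
    grf_impact_bw: float = 0.9
    grf_impact_center: float = 0.12
    grf_impact_width: float = 0.20
    grf_shear_bw: float = 0.25
    cop_span: tuple = (0.03, 0.97)  # COP path: fraction of heel->hallux line
    free_moment_peak: float = 1.5   # N*m
    contact_threshold: float = 20.0
    seed: int = 0

    def validate(self):
        if self.stance_duration <= 0:
            raise SpecError("stance duration must be positive")
        if self.marker_rate <= 0 or self.force_rate <= 0:
            raise SpecError("sampling rates must be positive")
        if self.noise_sigma < 0:
            raise SpecError("noise sigma must be non-negative")
        for jname, prof in self.profiles.items():
            if prof.max_amplitude() >= 90.0:
                raise SpecError(f"{jname} amplitude exceeds physiological bounds")
        if not 0 <= self.cop_span[0] < self.cop_span[1] <= 1.2:
            raise SpecError("cop_span must be increasing within [0, 1.2]")


@dataclass
class GroundTruth:
    """What the generator knows exactly, recorded before noise.

    ``angle_profiles`` are callables of stance fraction s (0 at true foot
    contact, 1 at true toe-off); ``angles_nodes`` samples them at 101
    evenly spaced nodes of the true stance window.  Because a
    threshold-based detector locates stance a fraction of a sample late,
    recovered series should be compared against
    :meth:`angles_on_window`, which evaluates the truth on the window the
    pipeline actually detected.
    """

    stance_start: float          # s, true first contact
    stance_duration: float       # s
    marker_rate: float
    angle_profiles: dict         # joint -> JointProfile (MULTI topology)
    angles_nodes: dict           # joint -> (101, 3) deg on the true window
    assignment: np.ndarray       # (T,) true GRF segment per marker sample
    shank_angle: tuple

    def stance_fraction(self, times):
        return (np.asarray(times, dtype=float) - self.stance_start) / self.stance_duration

    def angles_at_times(self, joint, times):
        return self.angle_profiles[joint].angles(self.stance_fraction(times))

    def angles_on_window(self, joint, window: StanceWindow, nodes: int = 101):
        t = np.linspace(window.first, window.last, nodes) / window.rate
        return self.angles_at_times(joint, t)

    def rates_on_window(self, joint, window: StanceWindow, nodes: int = 101):
        """Cardan angle rates, deg/s, on a detected window."""
        t = np.linspace(window.first, window.last, nodes) / window.rate
        s = self.stance_fraction(t)
        return self.angle_profiles[joint].rates(s) / self.stance_duration


# ---------------------------------------------------------------------------
# forward kinematics

def _rz(theta):
    theta = np.asarray(theta, dtype=float)
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros(theta.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


def _smoothstep(s):
    # tanh ramp: globally smooth, ~0 at s<=0, ~1 at s>=1
    return 0.5 * (1.0 + np.tanh(3.0 * (np.asarray(s, dtype=float) - 0.5)))


def _chain_rotations(spec: SyntheticTrialSpec, s, anat, signs):
    """Lab rotations of SHANK, RF, FF, TOE at stance fractions s."""
    th0, th1 = np.deg2rad(spec.shank_angle_deg)
    theta = th0 + (th1 - th0) * _smoothstep(s)
    Q = {"SHANK": _rz(theta)}
    chain = (("ankle", "SHANK", "RF"), ("midtarsal", "RF", "FF"), ("mtp", "FF", "TOE"))
    for jname, prox, dist in chain:
        clin = spec.profiles[jname].angles(s)          # clinical signs
        raw = clin * signs                              # ZXY cardan angles
        R_rel = cardan_zxy_compose(raw)
        A = anat[prox]
        Q[dist] = Q[prox] @ (A @ R_rel @ A.T)
    return Q


def _chain_positions(spec: SyntheticTrialSpec, times, geometry, anat, signs):
    """Marker positions (T, n, 3) plus segment rotations at given times."""
    g = {k: np.asarray(v, dtype=float) for k, v in geometry.items()}
    s = (np.asarray(times, dtype=float) - spec.lead) / spec.stance_duration
    Q = _chain_rotations(spec, s, anat, signs)
    ankle0 = 0.5 * (g["MMAL"] + g["LMAL"])
    mt0 = 0.5 * (g["NT"] + g["M5B"])
    mtp0 = g["M1H"]
    dx, dy = spec.ankle_travel_m
    a = ankle0[None, :] + np.stack([
        dx * _smoothstep(s),
        dy * np.sin(np.pi * np.clip(s, 0.0, 1.0)) ** 2,
        np.zeros_like(s)], axis=1)
    pivots = {"SHANK": (a, ankle0), "RF": (a, ankle0)}
    c_mt = a + np.einsum("tij,j->ti", Q["RF"], mt0 - ankle0)
    pivots["FF"] = (c_mt, mt0)
    c_mtp = c_mt + np.einsum("tij,j->ti", Q["FF"], mtp0 - mt0)
    pivots["TOE"] = (c_mtp, mtp0)
    names = list(geometry.keys())
    pos = np.empty((len(s), len(names), 3))
    for i, name in enumerate(names):
        seg = MARKER_SEGMENTS[name]
        origin, origin0 = pivots[seg]
        pos[:, i, :] = origin + np.einsum("tij,j->ti", Q[seg], g[name] - origin0)
    centers = {"ankle": a, "midtarsal": c_mt, "mtp": c_mtp}
    return names, pos, Q, centers


def _static_set(spec: SyntheticTrialSpec, rng) -> MarkerTrajectorySet:
    names = list(spec.geometry.keys())
    n = max(3, int(round(spec.static_duration * spec.marker_rate)))
    pos = np.tile(np.array([spec.geometry[k] for k in names], dtype=float),
                  (n, 1, 1))
    if spec.noise_sigma > 0:
        pos = pos + rng.normal(0.0, spec.noise_sigma, size=pos.shape)
    return MarkerTrajectorySet(spec.marker_rate, names, pos)


def _grf(spec: SyntheticTrialSpec, times, heel, hal):
    """Force, COP and free moment on the force-plate time base."""
    s = (np.asarray(times, dtype=float) - spec.lead) / spec.stance_duration
    bw = spec.mass * 9.81
    inside = (s > 0.0) & (s < 1.0)
    sc = np.clip(s, 0.0, 1.0)
    fy = bw * spec.grf_active_bw * np.sin(np.pi * sc)
    fy += bw * spec.grf_impact_bw * Bump(1.0, spec.grf_impact_center,
                                         spec.grf_impact_width).value(sc)
    fy = np.where(inside, fy, 0.0)
    fx = np.where(inside,
                  bw * spec.grf_shear_bw * (-np.sin(2 * np.pi * sc) * np.sin(np.pi * sc)),
                  0.0)
    fz = np.where(inside, 0.03 * bw * np.sin(2 * np.pi * sc), 0.0)
    force = np.stack([fx, fy, fz], axis=1)
    u = spec.cop_span[0] + (spec.cop_span[1] - spec.cop_span[0]) * sc
    cop = (1.0 - u)[:, None] * heel + u[:, None] * hal
    cop[:, 1] = 0.0
    cop[~inside] = np.nan
    free = np.where(inside,
                    spec.free_moment_peak * np.sin(np.pi * sc) * np.sin(2 * np.pi * sc),
                    0.0)
    mask = fy < spec.contact_threshold
    cop[mask] = np.nan
    free = np.where(mask, 0.0, free)
    return force, cop, free


def _true_assignment(spec, marker_times, centers, Q, anat, cop):
    """COP-region rule applied to the noise-free kinematics."""
    axes = (Q["RF"] @ anat["RF"])[:, :, 0].copy()
    axes[:, 1] = 0.0
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    out = np.full(len(marker_times), "", dtype=object)
    ok = np.isfinite(cop[:, 0])
    s = np.einsum("ti,ti->t", np.nan_to_num(cop, nan=0.0), axes)
    s_mt = np.einsum("ti,ti->t", centers["midtarsal"], axes)
    s_mtp = np.einsum("ti,ti->t", centers["mtp"], axes)
    ids = np.where(s < s_mt, "RF", np.where(s < s_mtp, "FF", "TOE"))
    out[ok] = ids[ok]
    return out


def generate_running_trial(spec: SyntheticTrialSpec | None = None,
                           config: PipelineConfig | None = None):
    """Generate one synthetic running trial.

    Returns ``(TrialBundle, GroundTruth)``.  Deterministic: the same spec
    (including its seed) yields byte-identical output.
    """
    spec = spec or SyntheticTrialSpec()
    spec.validate()
    config = config or DEFAULT_CONFIG
    rng = np.random.default_rng(spec.seed)
    signs = np.asarray(config.lab.angle_signs())

    static = _static_set(spec, rng)
    clean_static = MarkerTrajectorySet(
        spec.marker_rate, list(spec.geometry.keys()),
        np.tile(np.array([spec.geometry[k] for k in spec.geometry], dtype=float),
                (3, 1, 1)))
    model = make_model("MULTI", config)
    anat = build_anatomical_frames(clean_static, model, config.lab)

    total = spec.lead + spec.stance_duration + spec.tail
    n_m = int(round(total * spec.marker_rate)) + 1
    t_m = np.arange(n_m) / spec.marker_rate
    names, pos, Q, centers = _chain_positions(spec, t_m, spec.geometry, anat, signs)

    # force samples cover the marker record exactly (integer rate ratio)
    ratio = spec.force_rate / spec.marker_rate
    n_f = int(round((n_m - 1) * ratio)) + 1
    t_f = np.arange(n_f) / spec.force_rate
    _, pos_f, Q_f, centers_f = _chain_positions(spec, t_f, spec.geometry, anat, signs)
    i_ca, i_hal = names.index("CA"), names.index("HAL")
    force, cop_f, free = _grf(spec, t_f, pos_f[:, i_ca, :], pos_f[:, i_hal, :])
    forces = ForcePlateRecord(spec.force_rate, force, cop_f, free,
                              contact_threshold=spec.contact_threshold,
                              lab=config.lab)

    # ground truth before noise
    s_nodes = np.linspace(0.0, 1.0, 101)
    angles_nodes = {j: spec.profiles[j].angles(s_nodes) for j in spec.profiles}
    cop_m = np.stack([np.interp(t_m, t_f, np.nan_to_num(cop_f[:, k], nan=np.nan))
                      for k in range(3)], axis=1)
    # re-mask marker-rate COP by vertical force
    fy_m = np.interp(t_m, t_f, force[:, 1])
    cop_m[fy_m < spec.contact_threshold] = np.nan
    truth = GroundTruth(
        stance_start=spec.lead,
        stance_duration=spec.stance_duration,
        marker_rate=spec.marker_rate,
        angle_profiles={j: spec.profiles[j] for j in spec.profiles},
        angles_nodes=angles_nodes,
        assignment=_true_assignment(spec, t_m, centers, Q, anat, cop_m),
        shank_angle=spec.shank_angle_deg,
    )

    if spec.noise_sigma > 0:
        pos = pos + rng.normal(0.0, spec.noise_sigma, size=pos.shape)
    dynamic = MarkerTrajectorySet(spec.marker_rate, names, pos)
    ankle0 = 0.5 * (np.asarray(spec.geometry["MMAL"]) + np.asarray(spec.geometry["LMAL"]))
    heel = np.asarray(spec.geometry["CA"], dtype=float)
    hal = np.asarray(spec.geometry["HAL"], dtype=float)
    subject = SubjectMeta(
        mass=spec.mass,
        foot_length=float(np.linalg.norm(hal - heel)) + 0.03,
        shank_length=float(np.asarray(spec.geometry["SH4"])[1] - ankle0[1]) + 0.08,
        toe_length=float(np.linalg.norm(hal - np.asarray(spec.geometry["M1H"]))),
    )
    return TrialBundle(static, dynamic, forces, subject), truth


def generate_rigid_foot_trial(spec: SyntheticTrialSpec | None = None,
                              config: PipelineConfig | None = None):
    """Running trial whose foot moves as one rigid body: midtarsal and MTP
    amplitudes forced to zero, ankle profile kept."""
    spec = replace(spec) if spec else SyntheticTrialSpec()
    profiles = dict(spec.profiles)
    profiles["midtarsal"] = JointProfile()
    profiles["mtp"] = JointProfile()
    spec.profiles = profiles
    return generate_running_trial(spec, config)


def study_specs(n_subjects: int = 7, seed: int = 0, noise_sigma: float | None = None):
    """Specs for a cohort of synthetic subjects with inter-subject
    variation in mass, size, amplitude and timing (seeded)."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_subjects):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        scale = float(sub_rng.uniform(0.93, 1.07))
        geometry = {k: tuple(scale * np.asarray(v, dtype=float))
                    for k, v in DEFAULT_GEOMETRY.items()}
        amp = {j: float(sub_rng.uniform(0.82, 1.18)) for j in ("ankle", "midtarsal", "mtp")}
        profiles = {j: p.scaled(amp[j]) for j, p in default_profiles().items()}
        spec = SyntheticTrialSpec(
            mass=float(sub_rng.uniform(58.0, 85.0)),
            geometry=geometry,
            profiles=profiles,
            shank_angle_deg=(float(sub_rng.uniform(-17.0, -11.0)),
                             float(sub_rng.uniform(20.0, 28.0))),
            stance_duration=float(sub_rng.uniform(0.22, 0.26)),
            grf_active_bw=float(sub_rng.uniform(2.1, 2.5)),
            seed=sub_seed,
        )
        if noise_sigma is not None:
            spec.noise_sigma = noise_sigma
        specs.append(spec)
    return specs
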