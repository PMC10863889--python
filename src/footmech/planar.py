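"""Planar, dynamically consistent chain motions for verifying the
Newton-Euler recursion.

A chain of 1-3 rigid links pivots about a fixed base point in the
sagittal (x-y) plane.  Each link's absolute angle follows a sinusoid with
closed-form first and second derivatives, so every kinematic quantity the
recursion consumes (segment rotation, angular velocity/acceleration, COM
position/acceleration) is available analytically -- no numerical
differentiation anywhere.

In the consistent configuration the external load is constructed from the
prescribed motion by the forward free-body equations: the ground reaction
force equals the total rate of change of linear momentum minus gravity,
applied at a centre of pressure (plus a vertical free moment) chosen so
that the moment balance about the base joint closes exactly.  Feeding
that load back into the recursion must return zero residual force and
moment at the base and the analytic moments at every interior joint.

The single-link pendulum (no external load, fixed pivot) is the
work-energy fixture: the pivot does not translate, so the net work of the
base joint moment equals the change in total mechanical energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anthropometry import InertialParams
from .errors import SpecError
from .inverse_dynamics import LoadAssignmentSeries
from .io_formats import ForcePlateRecord

GRAVITY = np.array([0.0, -9.81, 0.0])


@dataclass
class PlanarLink:
    """One link: length (m), mass (kg), COM at ``com_r`` metres from the
    proximal joint along the link, principal inertia about the COM."""

    name: str
    length: float
    mass: float
    com_r: float
    inertia_diag: tuple = (1e-4, 2e-3, 2e-3)
    # absolute angle profile theta(t) = mean + amp * sin(2 pi f t + phase)
    mean_deg: float = 0.0
    amp_deg: float = 10.0
    freq_hz: float = 1.0
    phase: float = 0.0

    def theta(self, t):
        w = 2 * np.pi * self.freq_hz
        return np.deg2rad(self.mean_deg) + np.deg2rad(self.amp_deg) * np.sin(w * t + self.phase)

    def theta_dot(self, t):
        w = 2 * np.pi * self.freq_hz
        return np.deg2rad(self.amp_deg) * w * np.cos(w * t + self.phase)

    def theta_ddot(self, t):
        w = 2 * np.pi * self.freq_hz
        return -np.deg2rad(self.amp_deg) * w ** 2 * np.sin(w * t + self.phase)


@dataclass
class _Kin:
    R_anat: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    com: np.ndarray
    com_acc: np.ndarray


@dataclass
class PlanarCase:
    """Analytic kinematics + consistent loads, ready for the recursion."""

    rate: float
    times: np.ndarray
    chain: list                 # distal -> proximal segment names
    joints: list                # joints[i] = proximal joint of chain[i]
    kinematics: dict            # segment -> _Kin
    inertial: dict              # segment -> InertialParams
    joint_centers: dict         # joint -> (T,3)
    forces: ForcePlateRecord
    assignment: LoadAssignmentSeries
    true_moments: dict = field(default_factory=dict)   # joint -> (T,3)
    true_forces: dict = field(default_factory=dict)
    true_powers: dict = field(default_factory=dict)    # joint -> (T,)

    #: total mechanical energy (J) per sample, kinetic + potential
    energy: np.ndarray = None


def _rz(theta):
    c, s = np.cos(theta), np.sin(theta)
    R = np.zeros(np.shape(theta) + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


def default_links(n_segments=3):
    base = [
        PlanarLink("RF", 0.10, 0.50, 0.05, (5e-5, 4.2e-4, 4.2e-4),
                   mean_deg=-5.0, amp_deg=12.0, freq_hz=1.3, phase=0.0),
        PlanarLink("FF", 0.08, 0.40, 0.04, (4e-5, 2.1e-4, 2.1e-4),
                   mean_deg=5.0, amp_deg=9.0, freq_hz=1.3, phase=0.7),
        PlanarLink("TOE", 0.06, 0.10, 0.03, (8e-6, 3.0e-5, 3.0e-5),
                   mean_deg=0.0, amp_deg=15.0, freq_hz=1.3, phase=1.4),
    ]
    if not 1 <= n_segments <= 3:
        raise SpecError("planar chain supports 1-3 segments")
    return base[:n_segments]


def generate_planar_consistent_case(links=None, rate=600.0, duration=1.0,
                                    base_point=(0.0, 0.12, 0.0),
                                    with_grf=True) -> PlanarCase:
    """Build a planar chain case with exact kinematics and, when
    ``with_grf``, a dynamically consistent external load.

    ``links`` are ordered proximal -> distal (base link first); returned
    chain lists are distal -> proximal to match the recursion's order.
    """
    links = links or default_links()
    t = np.arange(int(round(rate * duration)) + 1) / rate
    T = len(t)
    base = np.asarray(base_point, dtype=float)

    # exact chain kinematics, proximal -> distal
    p = np.tile(base, (T, 1))          # current joint position
    v = np.zeros((T, 3))
    a = np.zeros((T, 3))
    joint_pos = [p.copy()]
    kin = {}
    vels = {}
    for link in links:
        th = link.theta(t)
        thd = link.theta_dot(t)
        thdd = link.theta_ddot(t)
        e = np.stack([np.cos(th), np.sin(th), np.zeros_like(th)], axis=1)
        ep = np.stack([-np.sin(th), np.cos(th), np.zeros_like(th)], axis=1)
        com = p + link.com_r * e
        com_v = v + link.com_r * (thd[:, None] * ep)
        com_a = a + link.com_r * (thdd[:, None] * ep - thd[:, None] ** 2 * e)
        omega = np.stack([np.zeros_like(thd), np.zeros_like(thd), thd], axis=1)
        alpha = np.stack([np.zeros_like(thdd), np.zeros_like(thdd), thdd], axis=1)
        kin[link.name] = _Kin(_rz(th), omega, alpha, com, com_a)
        vels[link.name] = com_v
        p = p + link.length * e
        v = v + link.length * (thd[:, None] * ep)
        a = a + link.length * (thdd[:, None] * ep - thd[:, None] ** 2 * e)
        joint_pos.append(p.copy())

    names = [lk.name for lk in links]
    joint_names = [f"J{i}" for i in range(len(links))]   # J0 = base
    centers = {joint_names[i]: joint_pos[i] for i in range(len(links))}
    inertial = {lk.name: InertialParams(lk.name, lk.mass, np.diag(lk.inertia_diag))
                for lk in links}

    # consistent external load from the forward free-body equations
    force = np.zeros((T, 3))
    cop = np.full((T, 3), np.nan)
    free = np.zeros(T)
    assign = np.full(T, "", dtype=object)
    if with_grf:
        F = np.zeros((T, 3))
        M0 = np.zeros((T, 3))
        for lk in links:
            k = kin[lk.name]
            F += lk.mass * (k.com_acc - GRAVITY)
            M0 += (np.einsum("ij,tj->ti", np.diag(lk.inertia_diag), k.alpha)
                   + np.cross(k.omega, np.einsum("ij,tj->ti", np.diag(lk.inertia_diag), k.omega))
                   + np.cross(k.com - base, lk.mass * (k.com_acc - GRAVITY)))
        fy = F[:, 1]
        if np.abs(fy).min() < 1.0:
            raise SpecError("prescribed motion too vigorous: vertical load "
                            "crosses zero, no consistent COP exists")
        d_y = -base[1]
        d_z = (d_y * F[:, 2] - M0[:, 0]) / fy
        d_x = (M0[:, 2] + d_y * F[:, 0]) / fy
        tau = M0[:, 1] - (d_z * F[:, 0] - d_x * F[:, 2])
        force = F
        cop = base[None, :] + np.stack([d_x, np.full(T, d_y), d_z], axis=1)
        free = tau
        # assign each sample to the link whose span contains the COP x
        jx = np.stack([centers[j][:, 0] for j in joint_names], axis=1)
        tip_x = joint_pos[-1][:, 0]
        sx = cop[:, 0]
        seg_idx = np.zeros(T, dtype=int)
        for i in range(1, len(links)):
            seg_idx[sx >= jx[:, i]] = i
        assign = np.array([names[i] for i in seg_idx], dtype=object)

    forces = ForcePlateRecord(rate, force, cop, free, contact_threshold=0.0)
    assignment = LoadAssignmentSeries(assign)

    case = PlanarCase(rate, t, names[::-1], joint_names[::-1], kin, inertial,
                      centers, forces, assignment)

    # analytic joint loads: direct moment balance of the distal subsystem,
    # evaluated with the exact kinematics (no recursion, no differencing)
    for i, jname in enumerate(joint_names):
        distal_links = links[i:]
        pj = centers[jname]
        Fj = np.zeros((T, 3))
        Mj = np.zeros((T, 3))
        for lk in distal_links:
            k = kin[lk.name]
            on = assign == lk.name
            Fext = np.zeros((T, 3))
            Fext[on] = force[on]
            copl = np.zeros((T, 3))
            copl[on] = cop[on]
            Mfree = np.zeros((T, 3))
            Mfree[on, 1] = free[on]
            I = np.diag(lk.inertia_diag)
            Fj += lk.mass * (k.com_acc - GRAVITY) - Fext
            Mj += (np.einsum("ij,tj->ti", I, k.alpha)
                   + np.cross(k.omega, np.einsum("ij,tj->ti", I, k.omega))
                   + np.cross(k.com - pj, lk.mass * (k.com_acc - GRAVITY))
                   - np.cross(copl - pj, Fext) - Mfree)
        case.true_forces[jname] = Fj
        case.true_moments[jname] = Mj
        w_prox = kin[links[i - 1].name].omega if i > 0 else 0.0
        w_rel = kin[links[i].name].omega - w_prox
        case.true_powers[jname] = np.einsum("ti,ti->t", Mj, w_rel)

    # total mechanical energy (for the work-energy fixture)
    E = np.zeros(T)
    for lk in links:
        k = kin[lk.name]
        vv = vels[lk.name]
        E += (0.5 * lk.mass * np.einsum("ti,ti->t", vv, vv)
              + 0.5 * lk.inertia_diag[2] * k.omega[:, 2] ** 2
              + lk.mass * 9.81 * k.com[:, 1])
    case.energy = E
    return case
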