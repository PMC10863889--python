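"""Core rigid-body kinematics.

Zero-lag Butterworth filtering with residual-analysis cutoff selection,
least-squares cluster pose estimation (Procrustes/Kabsch with reflection
correction), ZXY Cardan decomposition and composition, relative joint
rotations against a neutral trial, and angular velocity / acceleration
extraction.

Conventions: rotation matrices map segment coordinates into the lab frame
(lab <- segment); Cardan angles follow the sequence Z (flexion) -> X
(inversion) -> Y (adduction), in degrees; angular velocities are expressed
in the lab frame in rad/s.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .errors import (
    AlignmentError,
    DegenerateGeometryError,
    DiagnosticError,
    ParameterError,
)

__all__ = [
    "butter_zero_lag", "residual_cutoff", "estimate_pose",
    "estimate_pose_series", "cardan_zxy_decompose", "cardan_zxy_compose",
    "relative_joint_rotation", "angular_velocity", "angular_acceleration",
    "check_rotation",
]


# ---------------------------------------------------------------------------
# filtering

def butter_zero_lag(x, cutoff_hz, rate_hz, order=2, axis=0):
    """Low-pass Butterworth filter applied forward and reverse (zero lag).

    The effective magnitude response is the squared single-pass response,
    so the two-pass gain at the cutoff frequency is 0.5 for order 2.
    Endpoints are handled by odd reflection padding.

    Raises :class:`ParameterError` if the cutoff is at or above Nyquist.
    """
    x = np.asarray(x, dtype=float)
    nyq = rate_hz / 2.0
    if not 0.0 < cutoff_hz < nyq:
        raise ParameterError(f"cutoff {cutoff_hz} Hz outside (0, {nyq}) Hz")
    b, a = signal.butter(order, cutoff_hz / nyq)
    padlen = 3 * max(len(a), len(b))
    if x.shape[axis] <= padlen:
        raise ParameterError(
            f"series length {x.shape[axis]} too short for filter warm-up "
            f"({padlen} samples)")
    return signal.filtfilt(b, a, x, axis=axis, padtype="odd")


def residual_cutoff(x, rate_hz, candidates=None, order=2):
    """Select a low-pass cutoff by residual analysis (Winter-style).

    The RMS residual between the raw and filtered signal is computed over
    a grid of candidate cutoffs.  The high-frequency, noise-dominated part
    of the residual curve is fit with a straight line; its intercept with
    the residual axis estimates the noise floor, and the chosen cutoff is
    the lowest candidate whose residual does not exceed that intercept.

    Returns the selected cutoff in Hz.  If the curve never drops to the
    noise floor before the top of the grid (pure noise input) the largest
    candidate is returned with a warning.  Raises :class:`DiagnosticError`,
    with the residual curve attached, when no linear region is detectable.
    """
    x = np.asarray(x, dtype=float).ravel()
    nyq = rate_hz / 2.0
    if candidates is None:
        candidates = np.arange(1.0, 0.9 * nyq, 0.5)
    candidates = np.asarray(candidates, dtype=float)
    if candidates.min() <= 0 or candidates.max() >= nyq:
        raise ParameterError("candidate grid must lie inside (0, Nyquist)")
    if len(candidates) < 4:
        raise DiagnosticError(
            "candidate grid too short to identify a linear noise region",
            diagnostics={"candidates": candidates})
    res = np.array([
        np.sqrt(np.mean((x - butter_zero_lag(x, fc, rate_hz, order=order)) ** 2))
        for fc in candidates])
    rms = np.sqrt(np.mean((x - x.mean()) ** 2))
    if rms == 0 or res.max() < 1e-12 * max(rms, 1.0):
        return float(candidates[0])
    # linear (noise-dominated) region: upper half of the grid
    upper = candidates >= candidates[len(candidates) // 2]
    slope, intercept = np.polyfit(candidates[upper], res[upper], 1)
    intercept = max(float(intercept), 0.0)
    # tolerance: the noise intercept, or a small fraction of the signal for
    # effectively noise-free input
    tol = max(intercept, 0.01 * rms)
    below = res <= tol
    if below[0] or not below.any():
        # the residual curve never rises above the noise line (pure noise)
        # or never falls to it: both are degenerate
        warnings.warn("residual curve is noise-dominated; returning the "
                      "largest candidate cutoff as a sentinel")
        return float(candidates[-1])
    return float(candidates[np.argmax(below)])


# ---------------------------------------------------------------------------
# pose estimation

def _kabsch(ref, obs, weights=None):
    ref = np.asarray(ref, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if ref.shape != obs.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ParameterError("ref and obs must both have shape (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise ParameterError("pose estimation needs at least 3 markers")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    ref_c = ref - (w[:, None] * ref).sum(axis=0)
    obs_c = obs - (w[:, None] * obs).sum(axis=0)
    H = (w[:, None] * ref_c).T @ obs_c
    U, s, Vt = np.linalg.svd(H)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateGeometryError("marker cluster is collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = (w[:, None] * obs).sum(axis=0) - R @ (w[:, None] * ref).sum(axis=0)
    return R, t


def estimate_pose(ref, obs, weights=None):
    """Least-squares rigid transform mapping ``ref`` onto ``obs``.

    Minimises sum_i w_i ||R ref_i + t - obs_i||^2 over proper rotations R
    (SVD solution with determinant correction: a reflection branch is
    corrected, never returned).  Returns ``(R, t)``.
    """
    return _kabsch(ref, obs, weights)


def estimate_pose_series(ref, obs_series, weights=None):
    """Vectorised :func:`estimate_pose` over a time series.

    ref: (n, 3) calibration cluster; obs_series: (T, n, 3).
    Returns (R, t) with shapes (T, 3, 3) and (T, 3).
    """
    ref = np.asarray(ref, dtype=float)
    obs = np.asarray(obs_series, dtype=float)
    n = ref.shape[0]
    if n < 3:
        raise ParameterError("pose estimation needs at least 3 markers")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    ref_mean = (w[:, None] * ref).sum(axis=0)
    obs_mean = (w[None, :, None] * obs).sum(axis=1)
    ref_c = ref - ref_mean
    obs_c = obs - obs_mean[:, None, :]
    H = np.einsum("n,ni,tnj->tij", w, ref_c, obs_c)
    U, s, Vt = np.linalg.svd(H)
    if (s[:, 1] <= 1e-12 * np.maximum(s[:, 0], 1e-300)).any():
        raise DegenerateGeometryError("marker cluster is collinear")
    det = np.linalg.det(np.einsum("tji,tkj->tik", Vt, U))  # det(V U^T)
    D = np.repeat(np.eye(3)[None], len(obs), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("tji,tjk,tlk->til", Vt, D, U)  # V D U^T
    t = obs_mean - np.einsum("tij,j->ti", R, ref_mean)
    return R, t


def check_rotation(R, tol=1e-10):
    """Assert R (.., 3, 3) is a proper rotation within tol."""
    R = np.asarray(R)
    eye = np.eye(3)
    err = np.abs(np.einsum("...ij,...kj->...ik", R, R) - eye).max()
    if err > tol:
        raise DegenerateGeometryError(f"R R^T deviates from I by {err:.2e}")
    det = np.linalg.det(R)
    if np.abs(det - 1.0).max() > tol:
        raise DegenerateGeometryError("rotation determinant differs from +1")


# ---------------------------------------------------------------------------
# Cardan angles (ZXY)

def cardan_zxy_compose(angles_deg):
    """Rotation matrices from ZXY Cardan angles.

    angles_deg: (..., 3) as (flexion about z, inversion about x, adduction
    about y), degrees.  Returns (..., 3, 3) with R = Rz(g) Rx(a) Ry(b).
    """
    ang = np.deg2rad(np.asarray(angles_deg, dtype=float))
    g, a, b = ang[..., 0], ang[..., 1], ang[..., 2]
    cg, sg = np.cos(g), np.sin(g)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    R = np.empty(ang.shape[:-1] + (3, 3))
    R[..., 0, 0] = cg * cb - sg * sa * sb
    R[..., 0, 1] = -sg * ca
    R[..., 0, 2] = cg * sb + sg * sa * cb
    R[..., 1, 0] = sg * cb + cg * sa * sb
    R[..., 1, 1] = cg * ca
    R[..., 1, 2] = sg * sb - cg * sa * cb
    R[..., 2, 0] = -ca * sb
    R[..., 2, 1] = sa
    R[..., 2, 2] = ca * cb
    return R


def cardan_zxy_decompose(R):
    """ZXY Cardan angles (degrees) of rotation matrices (..., 3, 3).

    Returns (..., 3) as (flexion about z, inversion about x, adduction
    about y) such that R = Rz(g) Rx(a) Ry(b).  Near gimbal lock
    (|inversion| within ~1e-6 of 90 deg) a warning is issued and the
    flexion/adduction split is resolved by the convention adduction = 0.
    """
    R = np.asarray(R, dtype=float)
    s = np.clip(R[..., 2, 1], -1.0, 1.0)
    a = np.arcsin(s)
    near_lock = np.abs(np.abs(s) - 1.0) < 1e-12
    if near_lock.any():
        warnings.warn("gimbal lock: |inversion| ~ 90 deg; adduction set to 0")
    g = np.where(near_lock,
                 np.arctan2(R[..., 1, 0], R[..., 0, 0]),
                 np.arctan2(-R[..., 0, 1], R[..., 1, 1]))
    b = np.where(near_lock, 0.0, np.arctan2(-R[..., 2, 0], R[..., 2, 2]))
    return np.rad2deg(np.stack([g, a, b], axis=-1))


# ---------------------------------------------------------------------------
# joint rotations and derivatives

def relative_joint_rotation(prox_R, dist_R, prox0_R, dist0_R):
    """Joint rotation series: distal relative to proximal, offset so the
    neutral standing pose maps to the identity.

    R_joint(t) = [prox(t)^T dist(t)] [prox0^T dist0]^T
    """
    prox_R = np.asarray(prox_R, dtype=float)
    dist_R = np.asarray(dist_R, dtype=float)
    rel = np.einsum("...ji,...jk->...ik", prox_R, dist_R)
    rel0 = np.asarray(prox0_R).T @ np.asarray(dist0_R)
    return np.einsum("...ik,jk->...ij", rel, rel0)


def _vee(W):
    return np.stack([W[..., 2, 1] - W[..., 1, 2],
                     W[..., 0, 2] - W[..., 2, 0],
                     W[..., 1, 0] - W[..., 0, 1]], axis=-1) / 2.0


def angular_velocity(R_series, rate_hz):
    """Angular velocity (rad/s, lab frame) from a rotation series.

    Rdot is formed by central differences (one-sided at the ends) and
    omega extracted from the skew-symmetric part of Rdot R^T.
    """
    R = np.asarray(R_series, dtype=float)
    if R.ndim != 3 or R.shape[1:] != (3, 3):
        raise ParameterError("R_series must have shape (T, 3, 3)")
    if len(R) < 3:
        raise ParameterError("need at least 3 samples for derivatives")
    Rdot = np.gradient(R, axis=0) * rate_hz
    W = np.einsum("tij,tkj->tik", Rdot, R)
    return _vee(W)


def angular_acceleration(omega, rate_hz):
    """Angular acceleration by central differences of omega (T, 3)."""
    omega = np.asarray(omega, dtype=float)
    return np.gradient(omega, axis=0) * rate_hz


def derivative(series, rate_hz, order=1):
    """Central-difference time derivative along axis 0."""
    out = np.asarray(series, dtype=float)
    for _ in range(order):
        out = np.gradient(out, axis=0) * rate_hz
    return out
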