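"""Marker, force-plate and subject I/O.

Containers
----------
:class:`MarkerTrajectorySet`   named 3-D marker time series (metres, lab frame)
:class:`ForcePlateRecord`      GRF / COP / free-moment series (lab frame)
:class:`SubjectMeta`           body mass and limb dimensions
:class:`TrialBundle`           static + dynamic trial + forces + subject

File formats are plain text: TRC (tab separated, standard header rows with
rate and units) or a commented wide CSV for markers, and a commented CSV
for force-plate records.  Force files may carry either a ready-made COP or
raw plate moments, in which case the COP and vertical free moment are
computed here.  All coordinates are converted to metres on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import LabConfig
from .errors import (
    AlignmentError,
    FormatError,
    MetadataError,
    ParameterError,
    SchemaError,
)
from .rigid_body import butter_zero_lag

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}


# ---------------------------------------------------------------------------
# containers

@dataclass
class MarkerTrajectorySet:
    """Named 3-D marker trajectories sampled at a uniform rate.

    positions has shape (n_frames, n_markers, 3) in metres, lab frame.
    ``gaps`` is a boolean (n_frames, n_markers) mask, True where the sample
    is missing; coordinates must be finite wherever the mask is False.
    """

    rate: float
    names: list
    positions: np.ndarray
    gaps: np.ndarray = None
    unmapped: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise FormatError("positions must have shape (frames, markers, 3)")
        if len(self.names) != self.positions.shape[1]:
            raise FormatError("marker name count does not match positions")
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if self.gaps is None:
            self.gaps = ~np.isfinite(self.positions).all(axis=2)
        self.gaps = np.asarray(self.gaps, dtype=bool)
        ok = ~self.gaps
        if not np.isfinite(self.positions[ok]).all():
            raise FormatError("non-finite coordinates outside the gap mask")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"marker {name!r} not present") from None

    def get(self, name: str) -> np.ndarray:
        """Trajectory of one marker, shape (n_frames, 3)."""
        return self.positions[:, self.index(name), :]

    def subset(self, names) -> np.ndarray:
        """Stacked trajectories, shape (n_frames, len(names), 3)."""
        idx = [self.index(n) for n in names]
        return self.positions[:, idx, :]

    def mean_positions(self, names=None) -> dict:
        """Time-averaged position of each marker (gap-aware)."""
        names = list(self.names) if names is None else list(names)
        out = {}
        for n in names:
            i = self.index(n)
            ok = ~self.gaps[:, i]
            if not ok.any():
                raise SchemaError(f"marker {n!r} has no valid samples")
            out[n] = self.positions[ok, i, :].mean(axis=0)
        return out

    def filtered(self, cutoff_hz: float, order: int = 2) -> "MarkerTrajectorySet":
        """Zero-lag low-pass filtered copy (all markers, all axes)."""
        pos = butter_zero_lag(self.positions, cutoff_hz, self.rate, order=order, axis=0)
        return MarkerTrajectorySet(self.rate, list(self.names), pos,
                                   gaps=self.gaps.copy(), unmapped=list(self.unmapped))


@dataclass
class ForcePlateRecord:
    """Ground reaction force record in the lab frame.

    force: (n, 3) N; cop: (n, 3) m, NaN where vertical force is below the
    contact threshold; free_moment: (n,) N*m about the vertical axis.
    """

    rate: float
    force: np.ndarray
    cop: np.ndarray
    free_moment: np.ndarray
    contact_threshold: float = 20.0
    lab: LabConfig = field(default_factory=LabConfig)

    def __post_init__(self):
        self.force = np.atleast_2d(np.asarray(self.force, dtype=float))
        self.cop = np.atleast_2d(np.asarray(self.cop, dtype=float))
        self.free_moment = np.asarray(self.free_moment, dtype=float).ravel()
        n = len(self.force)
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if len(self.cop) != n or len(self.free_moment) != n:
            raise AlignmentError("force, cop, free_moment lengths differ")

    @property
    def n_samples(self) -> int:
        return len(self.force)

    @property
    def vertical_force(self) -> np.ndarray:
        return self.force[:, self.lab.up_axis]

    @property
    def contact_mask(self) -> np.ndarray:
        return self.vertical_force >= self.contact_threshold


@dataclass
class SubjectMeta:
    """Subject mass (kg) and limb dimensions (m)."""

    mass: float
    foot_length: float
    shank_length: float
    toe_length: float = 0.06
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mass <= 0:
            raise MetadataError("body mass must be positive")
        for name in ("foot_length", "shank_length", "toe_length"):
            if getattr(self, name) <= 0:
                raise MetadataError(f"{name} must be positive")


@dataclass
class TrialBundle:
    """One subject's calibration trial, dynamic trial and force record."""

    static: MarkerTrajectorySet
    dynamic: MarkerTrajectorySet
    forces: ForcePlateRecord
    subject: SubjectMeta

    def __post_init__(self):
        missing = set(self.static.names) - set(self.dynamic.names)
        if missing:
            raise SchemaError(
                f"static and dynamic trials use different marker schemas; "
                f"missing from dynamic: {sorted(missing)}")


# ---------------------------------------------------------------------------
# marker files

def _read_trc(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise FormatError("TRC file too short")
    header = lines[2].split("\t")
    try:
        rate = float(header[0])
        n_markers = int(header[3])
        units = header[4].strip().lower()
    except (IndexError, ValueError) as exc:
        raise FormatError(f"bad TRC header: {exc}") from exc
    labels = [x for x in lines[3].split("\t")[2:] if x.strip()]
    if len(labels) != n_markers:
        raise FormatError("TRC marker count does not match label row")
    data = []
    for line in lines[5:]:
        if not line.strip():
            continue
        parts = line.split("\t")
        vals = [float(p) if p.strip() else np.nan for p in parts[2:]]
        if len(vals) != 3 * n_markers:
            raise FormatError("inconsistent TRC data row length")
        data.append(vals)
    arr = np.asarray(data, dtype=float).reshape(len(data), n_markers, 3)
    return rate, labels, arr, units


def _read_marker_csv(path):
    meta = {}
    with open(path) as fh:
        text = fh.read()
    body = []
    for line in text.splitlines():
        if line.startswith("#"):
            if ":" in line:
                k, v = line.lstrip("# ").split(":", 1)
                meta[k.strip()] = v.strip()
        else:
            body.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body)))
    cols = [c for c in df.columns if c.lower() != "time"]
    labels = []
    for c in cols:
        base = c.rsplit("_", 1)
        if len(base) != 2 or base[1] not in ("X", "Y", "Z"):
            raise FormatError(f"marker CSV column {c!r} is not NAME_X/Y/Z")
        if base[0] not in labels:
            labels.append(base[0])
    for lab in labels:
        for ax in ("X", "Y", "Z"):
            if f"{lab}_{ax}" not in df.columns:
                raise FormatError(f"marker {lab!r} missing component {ax}")
    arr = np.stack([df[[f"{lab}_X", f"{lab}_Y", f"{lab}_Z"]].to_numpy(dtype=float)
                    for lab in labels], axis=1)
    if "rate_hz" in meta:
        rate = float(meta["rate_hz"])
    elif "time" in (c.lower() for c in df.columns):
        t = df[[c for c in df.columns if c.lower() == "time"][0]].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise FormatError("cannot infer a uniform rate from the time column")
        rate = 1.0 / dt[0]
    else:
        raise FormatError("marker CSV needs a '# rate_hz:' line or a time column")
    units = meta.get("units", "m").lower()
    return rate, labels, arr, units


def read_markers(path, schema=None, required=None, units=None) -> MarkerTrajectorySet:
    """Read marker trajectories from a TRC or CSV file.

    Parameters
    ----------
    schema : dict, optional
        Maps file labels to canonical labels.  Unmapped markers are kept
        but flagged in ``unmapped``.
    required : iterable of str, optional
        Canonical labels that must be present after mapping; a missing one
        raises :class:`SchemaError` naming every absent label.
    units : str, optional
        Override the unit declared in the file ('m', 'mm', 'cm').
    """
    path = str(path)
    if path.lower().endswith(".trc"):
        rate, labels, arr, file_units = _read_trc(path)
    else:
        rate, labels, arr, file_units = _read_marker_csv(path)
    u = (units or file_units or "m").lower()
    if u not in _UNIT_SCALE:
        raise FormatError(f"unknown unit {u!r}")
    arr = arr * _UNIT_SCALE[u]
    schema = schema or {}
    mapped = [schema.get(lab, lab) for lab in labels]
    unmapped = [m for lab, m in zip(labels, mapped) if lab not in schema and schema]
    if required:
        missing = sorted(set(required) - set(mapped))
        if missing:
            raise SchemaError(f"required markers absent: {missing}")
    return MarkerTrajectorySet(rate, mapped, arr, unmapped=unmapped)


def write_trc(mset: MarkerTrajectorySet, path, units="mm"):
    """Write a TRC file (default in millimetres, the format's convention)."""
    scale = 1.0 / _UNIT_SCALE[units]
    n, m = mset.n_frames, len(mset.names)
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{mset.rate:.6f}\t{mset.rate:.6f}\t{n}\t{m}\t{units}\t"
                 f"{mset.rate:.6f}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(mset.names) + "\t\t\n")
        comp = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(m))
        fh.write("\t\t" + comp + "\n")
        t = mset.times
        for i in range(n):
            row = mset.positions[i].ravel() * scale
            cells = ["" if not np.isfinite(v) else f"{v:.9f}" for v in row]
            fh.write(f"{i+1}\t{t[i]:.7f}\t" + "\t".join(cells) + "\n")


def write_marker_csv(mset: MarkerTrajectorySet, path):
    with open(path, "w") as fh:
        fh.write("# footmech markers v1\n")
        fh.write(f"# rate_hz: {mset.rate!r}\n")
        fh.write("# units: m\n")
        cols = ["time"] + [f"{n}_{ax}" for n in mset.names for ax in "XYZ"]
        fh.write(",".join(cols) + "\n")
        t = mset.times
        for i in range(mset.n_frames):
            vals = [f"{t[i]:.9f}"] + [f"{v:.12g}" for v in mset.positions[i].ravel()]
            fh.write(",".join(vals) + "\n")


# ---------------------------------------------------------------------------
# force files

def cop_from_plate_moments(force, moments, lab: LabConfig, threshold=20.0,
                           plate_origin=(0.0, 0.0, 0.0)):
    """COP and vertical free moment from moments about the plate origin.

    In the lab frame with up axis ``u`` and horizontal axes (h1, h2) in
    right-handed order, the plate moment about the origin of a force F at
    the surface point (c_h1, c_h2) is M = r x F, giving
    ``c_h1 = M_h2' / F_u`` style relations; the residual about the vertical
    axis is the free moment.  Returns (cop, free_moment) with COP NaN where
    the vertical force is below ``threshold``.
    """
    force = np.atleast_2d(force)
    moments = np.atleast_2d(moments)
    u = lab.up_axis
    fz = force[:, u]
    r0 = np.asarray(plate_origin, dtype=float)
    # shift moments to the plate surface point below the lab origin
    moments = moments - np.cross(r0, force)
    cop = np.full_like(force, np.nan)
    free = np.zeros(len(force))
    ok = fz >= threshold
    axes = [0, 1, 2]
    h = [a for a in axes if a != u]
    h1, h2 = h
    # r x F with r_u = 0: M_h1 = eps(h1,h2,u) r_h2 F_u, M_h2 = eps(h2,h1,u) r_h1 F_u
    eps = np.zeros((3, 3, 3))
    for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        eps[i, j, k] = 1.0
        eps[i, k, j] = -1.0
    c = np.zeros((len(force), 3))
    c[ok, h2] = moments[ok, h1] / (eps[h1, h2, u] * fz[ok])
    c[ok, h1] = moments[ok, h2] / (eps[h2, h1, u] * fz[ok])
    cop[ok] = c[ok]
    cop[:, u] = np.where(ok, 0.0, np.nan)
    rxf_u = (eps[u, h1, h2] * c[:, h1] * force[:, h2]
             + eps[u, h2, h1] * c[:, h2] * force[:, h1])
    free[ok] = moments[ok, u] - rxf_u[ok]
    return cop, free


_PLATE_TO_LAB = {
    # typical plate frame: z vertical up, x forward, y to the left;
    # rows map plate components to lab axes: lab_y = plate_z, lab_z = -plate_y
    "z-up": np.array([[1.0, 0.0, 0.0],
                      [0.0, 0.0, 1.0],
                      [0.0, -1.0, 0.0]]),
    "y-up": np.eye(3),
}


def read_forces(path, lab: LabConfig | None = None, threshold=20.0,
                plate_origin=(0.0, 0.0, 0.0)) -> ForcePlateRecord:
    """Read a force-plate CSV.

    Expected columns: ``time, Fx, Fy, Fz`` plus either ``COPx, COPy, COPz``
    (and optionally ``Tfree``) or raw plate moments ``Mx, My, Mz``.  A
    ``# vertical_axis: y|z`` comment declares the file's frame ('z' is the
    common plate convention and the default); data are mapped to the lab
    frame (y up) on read.  A ``# rate_hz:`` comment overrides the time
    column.
    """
    lab = lab or LabConfig()
    meta = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if ":" in line:
                    k, v = line.lstrip("# ").split(":", 1)
                    meta[k.strip()] = v.strip()
            else:
                body.append(line)
    df = pd.read_csv(io.StringIO("".join(body)))
    cols = {c.lower(): c for c in df.columns}
    if "rate_hz" in meta:
        rate = float(meta["rate_hz"])
    elif "time" in cols:
        t = df[cols["time"]].to_numpy(dtype=float)
        dt = np.diff(t)
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise FormatError("cannot infer a uniform rate from the time column")
        rate = 1.0 / dt[0]
    else:
        raise FormatError("force CSV needs a '# rate_hz:' line or a time column")

    vert = meta.get("vertical_axis", "z").lower()
    if vert not in ("y", "z"):
        raise FormatError(f"unknown vertical_axis {vert!r}")
    M = _PLATE_TO_LAB["z-up" if vert == "z" else "y-up"]

    def grab(names):
        missing = [n for n in names if n.lower() not in cols]
        if missing:
            return None
        return np.stack([df[cols[n.lower()]].to_numpy(dtype=float) for n in names], axis=1)

    force_p = grab(["Fx", "Fy", "Fz"])
    if force_p is None:
        raise FormatError("force CSV must contain Fx, Fy, Fz")
    force = force_p @ M.T
    fz = force[:, lab.up_axis]
    if (fz < -1.0).any():
        raise FormatError("vertical force is negative beyond tolerance; "
                          "check the sign convention / vertical_axis")

    cop_p = grab(["COPx", "COPy", "COPz"])
    if cop_p is not None:
        cop = cop_p @ M.T
        if "tfree" in cols:
            free = df[cols["tfree"]].to_numpy(dtype=float)
        else:
            free = np.zeros(len(force))
        mask = fz < threshold
        cop[mask] = np.nan
        free = np.where(mask, 0.0, free)
    else:
        mom_p = grab(["Mx", "My", "Mz"])
        if mom_p is None:
            raise FormatError("force CSV must contain COPx..z or Mx..z")
        moments = mom_p @ M.T
        cop, free = cop_from_plate_moments(force, moments, lab, threshold,
                                           plate_origin=plate_origin)
    return ForcePlateRecord(rate, force, cop, free,
                            contact_threshold=threshold, lab=lab)


def write_forces(rec: ForcePlateRecord, path):
    """Write a force record as a lab-frame (y-up) CSV with COP columns."""
    with open(path, "w") as fh:
        fh.write("# footmech forces v1\n")
        fh.write(f"# rate_hz: {rec.rate!r}\n")
        fh.write("# vertical_axis: y\n")
        fh.write("time,Fx,Fy,Fz,COPx,COPy,COPz,Tfree\n")
        t = np.arange(rec.n_samples) / rec.rate
        for i in range(rec.n_samples):
            f = rec.force[i]
            c = rec.cop[i]
            cvals = ["" if not np.isfinite(v) else f"{v:.12g}" for v in c]
            fh.write(f"{t[i]:.9f},{f[0]:.12g},{f[1]:.12g},{f[2]:.12g},"
                     + ",".join(cvals) + f",{rec.free_moment[i]:.12g}\n")


def resample_to_marker_rate(rec: ForcePlateRecord, target_rate: float,
                            interpolate: bool = False) -> ForcePlateRecord:
    """Decimate (or interpolate) a force record onto the marker time base.

    When the target rate divides the source rate the record is anti-alias
    filtered and decimated; otherwise ``interpolate=True`` is required and
    linear interpolation is used after the same anti-alias filtering.
    """
    if target_rate <= 0:
        raise ParameterError("target rate must be positive")
    if target_rate > rec.rate:
        raise AlignmentError("cannot resample upward to the marker rate")
    ratio = rec.rate / target_rate
    q = int(round(ratio))
    divisor = abs(ratio - q) < 1e-9
    if not divisor and not interpolate:
        raise AlignmentError(
            f"target rate {target_rate} Hz does not divide {rec.rate} Hz; "
            "pass interpolate=True")
    cutoff = 0.4 * target_rate
    force = butter_zero_lag(rec.force, cutoff, rec.rate, axis=0)
    free = butter_zero_lag(rec.free_moment, cutoff, rec.rate)
    # COP: fill outside-contact NaNs before filtering, re-mask afterwards
    cop = rec.cop.copy()
    ok = np.isfinite(cop[:, 0])
    if ok.any():
        idx = np.arange(len(cop))
        for k in range(3):
            cop[:, k] = np.interp(idx, idx[ok], cop[ok, k])
        cop = butter_zero_lag(cop, cutoff, rec.rate, axis=0)
    if divisor:
        sl = slice(0, None, q)
        force, cop, free = force[sl], cop[sl], free[sl]
    else:
        t_src = np.arange(rec.n_samples) / rec.rate
        t_new = np.arange(int(np.floor(t_src[-1] * target_rate)) + 1) / target_rate
        force = np.stack([np.interp(t_new, t_src, force[:, k]) for k in range(3)], axis=1)
        cop = np.stack([np.interp(t_new, t_src, cop[:, k]) for k in range(3)], axis=1)
        free = np.interp(t_new, t_src, free)
    out = ForcePlateRecord(target_rate, force, cop, free,
                           contact_threshold=rec.contact_threshold, lab=rec.lab)
    mask = ~out.contact_mask
    out.cop[mask] = np.nan
    out.free_moment[mask] = 0.0
    return out
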