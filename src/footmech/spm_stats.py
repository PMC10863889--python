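"""Statistical parametric mapping over 1-D stance-normalised fields.

Paired comparisons between two model conditions are run over whole
stance-time fields with family-wise error control:

* scalar (1-component) fields -- paired t field with a random-field-theory
  (RFT) critical threshold by default.  The RFT threshold solves
  ``alpha = rho_0(u) + R * rho_1(u)`` for the field maximum, where
  ``rho_0`` is the point survival function of the t distribution,
  ``rho_1(u) = sqrt(4 ln 2)/(2 pi) (1 + u^2/nu)^(-(nu-1)/2)`` the 1-D
  Euler-characteristic density of a t field, and ``R = (Q-1)/FWHM`` the
  resel count with smoothness estimated from the normalised residual
  fields.

* 3-component fields -- paired Hotelling's T^2 field.  The critical
  threshold is obtained from the exhaustive paired sign-flip permutation
  distribution of the field maximum (exact family-wise control under the
  paired null; with the study-sized n = 7 that is 2^7 = 128 flips).  A
  permutation mode is available for the t fields too, and small samples
  are exactly where the parametric assumptions strain.

Post-hoc scalar-component t fields use a Sidak-corrected level; scalar
(non-field) contrasts use classical paired t tests with Bonferroni
correction; normality is checked with the Shapiro-Wilk test.

Supra-threshold clusters are maximal runs of nodes beyond the threshold.
Parametric cluster p-values use the standard 1-D approximation
(expected cluster count from the EC density, exponential extent
distribution); permutation cluster p-values use the null distribution of
the maximum cluster extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ParameterError, PairingError

_SQRT_4LOG2 = np.sqrt(4.0 * np.log(2.0))


# ---------------------------------------------------------------------------
# containers

@dataclass
class FieldSample:
    """Subject x node (x component) sample of a stance-normalised field."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ParameterError("field sample must be (n, nodes[, comp])")
        if not np.isfinite(self.values).all():
            raise ParameterError("field sample contains missing values")

    @property
    def n_subjects(self):
        return self.values.shape[0]

    @property
    def n_nodes(self):
        return self.values.shape[1]

    @property
    def n_components(self):
        return 1 if self.values.ndim == 2 else self.values.shape[2]


@dataclass
class Cluster:
    start: int            # first node index beyond threshold
    end: int              # last node index (inclusive)
    p: float

    @property
    def extent(self):
        return self.end - self.start + 1


@dataclass
class SPMResult:
    test: str
    statistic: np.ndarray      # (nodes,)
    threshold: float
    clusters: list
    alpha: float
    df: tuple
    fwhm: float = np.nan
    method: str = "rft"
    two_tailed: bool = True

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0

    def to_dict(self):
        return {
            "test": self.test, "alpha": self.alpha, "method": self.method,
            "threshold": float(self.threshold), "df": list(self.df),
            "fwhm": float(self.fwhm),
            "statistic": [float(v) for v in self.statistic],
            "clusters": [{"start": int(c.start), "end": int(c.end),
                          "p": float(c.p)} for c in self.clusters],
        }


# ---------------------------------------------------------------------------
# smoothness and RFT densities

def estimate_fwhm(residuals) -> float:
    """Smoothness (FWHM, in nodes) of residual fields.

    residuals: (n, nodes) or (n, nodes, comp); components are stacked as
    extra residual fields.  Standard normalised-gradient estimator.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim == 3:
        R = np.concatenate([R[..., k] for k in range(R.shape[2])], axis=0)
    ssq = (R ** 2).sum(axis=0)
    dx = np.gradient(R, axis=1)
    v = (dx ** 2).sum(axis=0)
    good = ssq > np.finfo(float).eps
    if not good.any():
        return float(R.shape[1])
    ratio = v[good] / ssq[good]
    rpn = np.sqrt(ratio / (4.0 * np.log(2.0)))   # resels per node
    fwhm = 1.0 / rpn.mean()
    return float(min(fwhm, R.shape[1]))


def _ec_density_t(u, nu):
    """1-D EC density of a t field (per unit resel)."""
    return (_SQRT_4LOG2 / (2.0 * np.pi)
            * (1.0 + u ** 2 / nu) ** (-(nu - 1.0) / 2.0))


def rft_threshold_t(alpha, nu, nodes, fwhm, two_tailed=True) -> float:
    """Critical height of a smooth t field at family-wise level alpha."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0,1)")
    resels = (nodes - 1) / fwhm
    target = alpha / 2.0 if two_tailed else alpha

    def f(u):
        return stats.t.sf(u, nu) + resels * _ec_density_t(u, nu) - target

    lo, hi = 1e-3, 1e3
    return float(optimize.brentq(f, lo, hi))


def _clusters_above(stat, threshold, two_tailed=True):
    z = np.abs(stat) if two_tailed else stat
    above = z > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]))
    return [(int(a), int(b - 1)) for a, b in zip(edges[::2], edges[1::2])]


def _rft_cluster_p(extent_nodes, u, nu, nodes, fwhm, two_tailed=True):
    """Parametric cluster-level p for a t-field cluster of given extent."""
    resels = (nodes - 1) / fwhm
    EN = resels * _ec_density_t(u, nu) + stats.t.sf(u, nu)
    if two_tailed:
        EN *= 2.0
    point = stats.t.sf(u, nu) * (2.0 if two_tailed else 1.0)
    ES_resels = resels * point
    if EN <= 0 or ES_resels <= 0:
        return 1.0
    mean_extent = ES_resels / EN
    k = extent_nodes / fwhm
    p_ext = np.exp(-k / max(mean_extent, 1e-12))
    return float(1.0 - np.exp(-EN * p_ext))


# ---------------------------------------------------------------------------
# paired statistics per node

def _paired_diff(a: FieldSample, b: FieldSample):
    if a.values.shape != b.values.shape:
        raise PairingError("paired samples must share shape (matched subjects)")
    if a.n_subjects < 2:
        raise PairingError("paired tests need at least 2 subjects")
    return a.values - b.values


def t_field(d) -> np.ndarray:
    """Paired t statistic per node from differences d (n, nodes)."""
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero = sd <= np.finfo(float).eps * np.abs(d).max(initial=1.0)
    if zero.any():
        warnings.warn("zero-variance nodes: t statistic set to 0 by convention")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, 0.0, m / (sd / np.sqrt(n)))
    return t


def hotelling_t2_field(d) -> np.ndarray:
    """Paired Hotelling T^2 per node from differences d (n, nodes, p)."""
    d = np.asarray(d, dtype=float)
    n, _, p = d.shape
    if n < p + 1:
        raise PairingError(f"Hotelling needs n >= components+1 ({p + 1})")
    m = d.mean(axis=0)
    c = d - m
    S = np.einsum("tnp,tnq->npq", c, c) / (n - 1)
    return _t2_solve(S, m, n)


def _t2_solve(S, m, n):
    try:
        x = np.linalg.solve(S, m[..., None])[..., 0]
    except np.linalg.LinAlgError:
        warnings.warn("singular node covariance: using pseudo-inverse")
        x = np.einsum("...pq,...q->...p", np.linalg.pinv(S), m)
    return n * np.einsum("...p,...p->...", m, x)


# ---------------------------------------------------------------------------
# permutation machinery (paired sign flips)

def _sign_matrix(n, max_perms, rng):
    if 2 ** n <= max_perms:
        bits = np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]
        return 1.0 - 2.0 * (bits & 1)
    rng = np.random.default_rng(rng)
    return 1.0 - 2.0 * rng.integers(0, 2, size=(max_perms, n))


def _perm_max_t(d, signs):
    """Max |t| over nodes for each sign-flip (vectorised; the per-subject
    squared terms are sign-invariant)."""
    n, _ = d.shape
    ss = (d ** 2).sum(axis=0)
    M = signs @ d / n                      # (K, nodes)
    var = (ss[None, :] - n * M ** 2) / (n - 1)
    var = np.maximum(var, np.finfo(float).tiny)
    t = M / np.sqrt(var / n)
    return np.abs(t), t


def _perm_max_t2(d, signs):
    n, q, p = d.shape
    G = np.einsum("tnp,tnq->npq", d, d)     # sign-invariant Gram
    M = np.einsum("kt,tnp->knp", signs, d) / n
    S = (G[None] - n * np.einsum("knp,knq->knpq", M, M)) / (n - 1)
    return _t2_solve(S, M, n)


def permutation_threshold(stat_fields, alpha):
    """(1-alpha) quantile of the permutation max-statistic distribution,
    chosen so the family-wise rate does not exceed alpha."""
    maxima = stat_fields.max(axis=1)
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


# ---------------------------------------------------------------------------
# public tests

def spm_paired_t(a, b, alpha=0.05, method="rft", two_tailed=True,
                 max_perms=1024, seed=0) -> SPMResult:
    """SPM paired t test between two matched 1-component field samples."""
    a = a if isinstance(a, FieldSample) else FieldSample(a)
    b = b if isinstance(b, FieldSample) else FieldSample(b)
    if a.n_components != 1:
        raise ParameterError("spm_paired_t expects 1-component fields")
    d = _paired_diff(a, b)
    n, nodes = d.shape
    nu = n - 1
    t = t_field(d)
    resid = d - d.mean(axis=0)
    fwhm = estimate_fwhm(resid)
    if method == "rft":
        u = rft_threshold_t(alpha, nu, nodes, fwhm, two_tailed)
        clusters = [Cluster(s, e, _rft_cluster_p(e - s + 1, u, nu, nodes, fwhm,
                                                 two_tailed))
                    for s, e in _clusters_above(t, u, two_tailed)]
    elif method == "perm":
        signs = _sign_matrix(n, max_perms, seed)
        tp, _ = _perm_max_t(d, signs)
        if not two_tailed:
            _, tp = _perm_max_t(d, signs)
        u = permutation_threshold(tp, alpha)
        spans = _clusters_above(t, u, two_tailed)
        clusters = [Cluster(s, e, _perm_cluster_p(tp, u, e - s + 1))
                    for s, e in spans]
    else:
        raise ParameterError(f"unknown method {method!r}")
    # every supra-threshold cluster is family-significant by the height
    # threshold; the approximate cluster-level p is capped at alpha
    clusters = [Cluster(c.start, c.end, min(c.p, alpha)) for c in clusters]
    return SPMResult("paired_t", t, u, clusters, alpha, (1.0, float(nu)),
                     fwhm=fwhm, method=method, two_tailed=two_tailed)


def _perm_cluster_p(perm_fields, threshold, extent):
    """P(max null cluster extent >= extent) over the permutation fields."""
    K = perm_fields.shape[0]
    count = 0
    above = perm_fields > threshold
    pad = np.zeros((K, 1), dtype=int)
    d = np.diff(np.concatenate([pad, above.astype(int), pad], axis=1), axis=1)
    for k in range(K):
        starts = np.flatnonzero(d[k] == 1)
        stops = np.flatnonzero(d[k] == -1)
        if len(starts) and (stops - starts).max() >= extent:
            count += 1
    return (count + 1) / (K + 1)


def spm_paired_hotelling(a, b, alpha=0.05, method="perm", max_perms=1024,
                         seed=0) -> SPMResult:
    """SPM paired Hotelling's T^2 test between matched 3-component fields."""
    a = a if isinstance(a, FieldSample) else FieldSample(a)
    b = b if isinstance(b, FieldSample) else FieldSample(b)
    d = _paired_diff(a, b)
    if d.ndim == 2:
        d = d[..., None]
    n, nodes, p = d.shape
    if n < p + 1:
        raise PairingError("Hotelling needs at least components+1 subjects")
    t2 = hotelling_t2_field(d)
    resid = d - d.mean(axis=0)
    fwhm = estimate_fwhm(resid)
    if method != "perm":
        raise ParameterError(
            "only the exact sign-flip permutation threshold is provided for "
            "the T^2 field")
    signs = _sign_matrix(n, max_perms, seed)
    perm = _perm_max_t2(d, signs)
    u = permutation_threshold(perm, alpha)
    spans = _clusters_above(t2, u, two_tailed=False)
    clusters = [Cluster(s, e, min(_perm_cluster_p(perm, u, e - s + 1), alpha))
                for s, e in spans]
    return SPMResult("paired_hotelling_T2", t2, u, clusters, alpha,
                     (float(p), float(n - 1)), fwhm=fwhm, method="perm",
                     two_tailed=False)


# ---------------------------------------------------------------------------
# scalar tests and corrections

def sidak_alpha(family_alpha: float, k: int) -> float:
    """Sidak-corrected per-comparison level: 1 - (1 - alpha)^(1/k)."""
    if not 0.0 < family_alpha < 1.0:
        raise ParameterError("family alpha must be in (0,1)")
    if k < 1:
        raise ParameterError("k must be >= 1")
    return 1.0 - (1.0 - family_alpha) ** (1.0 / k)


def scalar_paired_t(a, b, corrections: int = 1, alpha: float = 0.05):
    """Classical paired t test with a Bonferroni-adjusted threshold.

    Returns ``(t, p, corrected_alpha)``; the comparison is judged
    significant when ``p < corrected_alpha``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError("scalar paired t needs matched 1-D samples")
    if len(a) < 2:
        raise PairingError("need at least 2 pairs")
    if corrections < 1:
        raise ParameterError("corrections must be >= 1")
    d = a - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0, alpha / corrections
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), alpha / corrections


def normality_check(x, alpha: float = 0.05):
    """Shapiro-Wilk normality check: returns (statistic, p, passed).

    A constant sample cannot be tested; by convention it fails with
    p = 0 and a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 3:
        raise ParameterError("normality check needs n >= 3")
    if np.ptp(x) == 0.0:
        warnings.warn("constant sample: normality check fails by convention")
        return np.nan, 0.0, False
    w, p = stats.shapiro(x)
    return float(w), float(p), bool(p > alpha)


# ---------------------------------------------------------------------------
# smooth Gaussian fields (null calibration and tests)

def smooth_gaussian_fields(n, nodes, fwhm, rng, n_components=1):
    """Unit-variance smooth Gaussian random fields (n, nodes[, comp]).

    White noise convolved with a Gaussian kernel of the requested FWHM,
    then rescaled per node so edge effects do not reduce variance.
    """
    rng = np.random.default_rng(rng)
    sd = fwhm / _SQRT_4LOG2 / np.sqrt(2.0)
    half = int(np.ceil(4 * sd))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd) ** 2)
    shape = (n, nodes + 2 * half) if n_components == 1 else (n, nodes + 2 * half, n_components)
    w = rng.standard_normal(shape)
    sm = np.apply_along_axis(lambda v: np.convolve(v, k, mode="same"), 1, w)
    sm = sm[:, half:half + nodes]
    norm = np.sqrt((k ** 2).sum())
    return sm / norm
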