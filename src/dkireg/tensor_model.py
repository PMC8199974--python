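"""The diffusion-kurtosis signal representation and its derived scalars.

The diffusion-weighted signal of a voxel is represented by its second and
fourth cumulants,

    log S(b, g) = log S0 - b * sum_ij g_i g_j D_ij
                  + (b^2 / 6) * Dbar^2 * sum_ijkl g_i g_j g_k g_l W_ijkl,

with ``D`` the symmetric diffusion tensor (6 unique elements, um^2/ms),
``W`` the fully symmetric kurtosis tensor (15 unique elements,
dimensionless), ``b`` the diffusion weighting in ms/um^2, ``g`` a unit
gradient direction, and ``Dbar = trace(D)/3`` the mean diffusivity.

Parameterization note: the fitted parameter vector uses the extended
b-matrix convention in which the kurtosis block carries ``V = Dbar^2 * W``
so that the log-signal is *linear* in the 22-vector
``(log S0, D_11, D_22, D_33, D_12, D_13, D_23, V_1111, ...)``.
:func:`DKIParams.to_theta` / :func:`DKIParams.from_theta` convert between
the two bit-exactly.  Unique-element ordering is fixed:

    dt: (D11, D22, D33, D12, D13, D23)
    kt: (W1111, W2222, W3333, W1112, W1113, W1222, W1333, W2223, W2333,
         W1122, W1133, W2233, W1123, W1223, W1233)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._directions import circle_perpendicular, fibonacci_sphere

__all__ = [
    "GradientScheme",
    "DKIParams",
    "ScalarMaps",
    "DT_INDICES",
    "KT_INDICES",
    "DT_MULT",
    "KT_MULT",
    "build_design_matrix",
    "forward_signal",
    "apparent_coefficients",
    "mean_kurtosis_directional",
    "mean_kurtosis_tensor",
    "directional_kurtosis_metrics",
    "dti_metrics",
    "psi_correction",
    "delta_frobenius",
]

# unique-element index tuples (0-based axes) and permutation multiplicities
DT_INDICES = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
DT_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

KT_INDICES = [
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (0, 2, 2, 2),
    (1, 1, 1, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
]
KT_MULT = np.array([1.0, 1.0, 1.0,
                    4.0, 4.0, 4.0, 4.0, 4.0, 4.0,
                    6.0, 6.0, 6.0,
                    12.0, 12.0, 12.0])

# indices of W1122, W1133, W2233 within the kt vector
_KT_SQUARE_PAIRS = (9, 10, 11)

#: signalling value for metrics that are undefined in a degenerate voxel
DEGENERATE = np.nan


class IdentifiabilityError(ValueError):
    """Raised when a gradient scheme cannot identify all 22 parameters."""


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume diffusion weightings and unit gradient directions.

    Parameters
    ----------
    bvals
        Diffusion weightings, ms/um^2, shape ``(n,)``.
    bvecs
        Unit direction per volume, shape ``(n, 3)``.  Directions of b=0
        volumes may be zero vectors.
    shell_ids
        Integer shell label per volume (same b-value => same label).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    shell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError("bvals and bvecs disagree on volume count")
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        norms = np.linalg.norm(bvecs, axis=1)
        dw = bvals > 0
        if np.any(np.abs(norms[dw] - 1.0) > 1e-6):
            raise ValueError("non-unit gradient direction at b > 0")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)
        if self.shell_ids is None:
            from .powder import group_shells  # deferred: avoids import cycle
            object.__setattr__(self, "shell_ids", group_shells(bvals))
        else:
            object.__setattr__(
                self, "shell_ids",
                np.asarray(self.shell_ids, dtype=int).reshape(-1))

    @property
    def n_volumes(self) -> int:
        return int(self.bvals.shape[0])

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dw_mask(self) -> np.ndarray:
        return self.bvals > 0

    def fingerprint(self) -> dict:
        """Shell-level summary used to guard model transfer across protocols."""
        shells = {}
        for sid in np.unique(self.shell_ids):
            sel = self.shell_ids == sid
            shells[int(sid)] = {
                "b": float(np.mean(self.bvals[sel])),
                "n_dirs": int(np.sum(sel)),
            }
        return {"shells": shells, "n_volumes": self.n_volumes}


@dataclass
class DKIParams:
    """The 21 tensor degrees of freedom plus the log b=0 amplitude."""

    log_s0: float
    dt: np.ndarray  # 6 unique D_ij, um^2/ms
    kt: np.ndarray  # 15 unique W_ijkl, dimensionless

    def __post_init__(self):
        self.dt = np.asarray(self.dt, dtype=float).reshape(6)
        self.kt = np.asarray(self.kt, dtype=float).reshape(15)

    @property
    def md(self) -> float:
        """Mean diffusivity, trace(D)/3."""
        return float(np.sum(self.dt[:3]) / 3.0)

    def d_matrix(self) -> np.ndarray:
        d = np.empty((3, 3))
        d[0, 0], d[1, 1], d[2, 2] = self.dt[:3]
        d[0, 1] = d[1, 0] = self.dt[3]
        d[0, 2] = d[2, 0] = self.dt[4]
        d[1, 2] = d[2, 1] = self.dt[5]
        return d

    def to_theta(self) -> np.ndarray:
        """22-vector (log_s0, dt, Dbar^2 * kt) matching the design matrix."""
        return np.concatenate(
            [[self.log_s0], self.dt, self.md ** 2 * self.kt])

    @classmethod
    def from_theta(cls, theta: np.ndarray) -> "DKIParams":
        theta = np.asarray(theta, dtype=float).reshape(22)
        dt = theta[1:7]
        md = np.sum(dt[:3]) / 3.0
        md2 = md * md
        kt = theta[7:] / md2 if md2 > 0 else np.full(15, np.nan)
        return cls(log_s0=float(theta[0]), dt=dt.copy(), kt=kt)


@dataclass
class ScalarMaps:
    """Derived per-voxel scalar metrics (arrays share one spatial shape)."""

    md: np.ndarray
    ad: np.ndarray
    rd: np.ndarray
    fa: np.ndarray
    mk: np.ndarray
    ak: np.ndarray
    rk: np.ndarray
    delta: np.ndarray
    psi: np.ndarray

    def as_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("md", "ad", "rd", "fa", "mk", "ak", "rk",
                          "delta", "psi")}


def _dt_monomials(g: np.ndarray) -> np.ndarray:
    """Rows of g_i g_j products with pair multiplicity, shape (n, 6)."""
    g = np.atleast_2d(g)
    cols = [g[:, i] * g[:, j] for i, j in DT_INDICES]
    return np.column_stack(cols) * DT_MULT


def _kt_monomials(g: np.ndarray) -> np.ndarray:
    """Rows of g_i g_j g_k g_l products with multiplicity, shape (n, 15)."""
    g = np.atleast_2d(g)
    cols = [g[:, i] * g[:, j] * g[:, k] * g[:, l]
            for i, j, k, l in KT_INDICES]
    return np.column_stack(cols) * KT_MULT


def build_design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Extended b-matrix design mapping the 22-vector theta to log-signals.

    Row for volume ``(b, g)``:
    ``[1, -b * m_ij g_i g_j, (b^2/6) * m_ijkl g_i g_j g_k g_l]`` with
    multiplicities ``m`` counting distinct index permutations (2 for
    off-diagonal D, {1,4,6,12} for W).  The kurtosis block multiplies the
    parameter ``V = Dbar^2 * W``; log S = B @ (log_s0, dt, V).
    """
    if scheme.n_volumes < 22:
        raise IdentifiabilityError(
            f"{scheme.n_volumes} volumes < 22 parameters")
    if np.unique(np.round(scheme.bvals, 6)).size < 3:
        raise IdentifiabilityError(
            "at least 3 distinct b-values are required")
    b = scheme.bvals[:, None]
    g = scheme.bvecs
    ones = np.ones((scheme.n_volumes, 1))
    d_block = -b * _dt_monomials(g)
    k_block = (b ** 2 / 6.0) * _kt_monomials(g)
    return np.hstack([ones, d_block, k_block])


def forward_signal(params: DKIParams, scheme: GradientScheme) -> np.ndarray:
    """Noise-free signal amplitudes S(b, g); exact inverse of a noiseless fit."""
    # intentionally bypasses build_design_matrix's identifiability guard:
    # forward evaluation is valid for any scheme size
    b = scheme.bvals[:, None]
    g = scheme.bvecs
    theta = params.to_theta()
    log_s = (theta[0]
             + (-b * _dt_monomials(g)) @ theta[1:7]
             + ((b ** 2 / 6.0) * _kt_monomials(g)) @ theta[7:])
    return np.exp(log_s)


def apparent_coefficients(params: DKIParams,
                          direction: np.ndarray) -> tuple[float, float]:
    """Apparent diffusivity and kurtosis along one unit direction.

    ``D_app = g^T D g``; ``K_app = (Dbar^2 / D_app^2) * W(g)`` with ``W(g)``
    the full 81-term contraction of the kurtosis tensor (evaluated through
    the 15 unique elements and their multiplicities).

    A non-positive ``D_app`` makes the kurtosis undefined; the pair
    ``(D_app, nan)`` is returned so callers can flag the voxel instead of
    silently propagating.
    """
    g = np.asarray(direction, dtype=float).reshape(3)
    if abs(np.linalg.norm(g) - 1.0) > 1e-6:
        raise ValueError("direction must be a unit vector")
    d_app = float((_dt_monomials(g) @ params.dt)[0])
    if d_app <= 0:
        return d_app, DEGENERATE
    w_g = float((_kt_monomials(g) @ params.kt)[0])
    md = params.md
    return d_app, (md * md / (d_app * d_app)) * w_g


def _kapp_many(params: DKIParams, dirs: np.ndarray) -> np.ndarray:
    """Vectorized K_app over a direction set; nan where D_app <= 0."""
    d_app = _dt_monomials(dirs) @ params.dt
    w_g = _kt_monomials(dirs) @ params.kt
    md2 = params.md ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        k = md2 * w_g / (d_app * d_app)
    k[d_app <= 0] = DEGENERATE
    return k


def mean_kurtosis_directional(params: DKIParams, n_dirs: int = 100) -> float:
    """Mean kurtosis: average of K_app over a deterministic spherical design.

    This is the reported mean kurtosis.  Returns nan (voxel degenerate) if
    any direction has non-positive apparent diffusivity.
    """
    if n_dirs < 45:
        raise ValueError("n_dirs must be >= 45 for a stable spherical average")
    k = _kapp_many(params, fibonacci_sphere(n_dirs))
    if np.any(~np.isfinite(k)):
        return DEGENERATE
    return float(np.mean(k))


def mean_kurtosis_tensor(params: DKIParams) -> float:
    """Closed-form tensor mean kurtosis (trace-based mean of W).

    ``MKT = (W1111 + W2222 + W3333 + 2 W1122 + 2 W1133 + 2 W2233) / 5``.
    Smooth in the parameters, hence the form used inside the regularization
    penalty.  Coincides with the directional mean kurtosis when D is
    isotropic.
    """
    kt = params.kt
    return float((kt[0] + kt[1] + kt[2]
                  + 2.0 * (kt[9] + kt[10] + kt[11])) / 5.0)


def mkt_from_theta(theta: np.ndarray) -> float:
    """MKT evaluated directly on the 22-vector used by the fitters."""
    dt = theta[1:7]
    md = (dt[0] + dt[1] + dt[2]) / 3.0
    v = theta[7:]
    s = v[0] + v[1] + v[2] + 2.0 * (v[9] + v[10] + v[11])
    return float(s / (5.0 * md * md))


def mkt_theta_gradient(theta: np.ndarray) -> np.ndarray:
    """Gradient of :func:`mkt_from_theta` with respect to theta."""
    grad = np.zeros(22)
    dt = theta[1:7]
    md = (dt[0] + dt[1] + dt[2]) / 3.0
    v = theta[7:]
    s = v[0] + v[1] + v[2] + 2.0 * (v[9] + v[10] + v[11])
    md2 = md * md
    # d/dD_ii: s/(5 md^2) has md(theta) = (t1+t2+t3)/3
    grad[1:4] = -2.0 * s / (5.0 * md2 * md) / 3.0
    grad[7 + 0] = grad[7 + 1] = grad[7 + 2] = 1.0 / (5.0 * md2)
    for j in _KT_SQUARE_PAIRS:
        grad[7 + j] = 2.0 / (5.0 * md2)
    return grad


def directional_kurtosis_metrics(params: DKIParams,
                                 n_perp: int = 64) -> tuple[float, float]:
    """Axial and radial kurtosis.

    AK is K_app along the principal eigenvector of D; RK is the mean of
    K_app over ``n_perp`` (>= 64) evenly spaced directions in the
    perpendicular plane.  On an exactly degenerate principal direction the
    lexicographically smallest axis is used as tie-break.
    """
    if n_perp < 64:
        raise ValueError("n_perp must be >= 64")
    evals, evecs = np.linalg.eigh(params.d_matrix())
    # eigh sorts ascending; principal = last. Exact tie: smallest axis index.
    order = np.argsort(evals, kind="stable")
    e1 = evecs[:, order[-1]]
    _, ak = apparent_coefficients(params, e1)
    perp = circle_perpendicular(e1, n_perp)
    rk_vals = _kapp_many(params, perp)
    rk = DEGENERATE if np.any(~np.isfinite(rk_vals)) else float(
        np.mean(rk_vals))
    return ak, rk


def dti_metrics(params: DKIParams) -> tuple[float, float, float, float]:
    """(MD, AD, RD, FA) from the eigen-decomposition of D."""
    if not np.all(np.isfinite(params.dt)):
        raise ValueError("non-finite diffusion tensor")
    evals = np.linalg.eigvalsh(params.d_matrix())  # ascending
    md = float(np.mean(evals))
    ad = float(evals[2])
    rd = float((evals[0] + evals[1]) / 2.0)
    num = np.sum((evals - md) ** 2)
    den = np.sum(evals ** 2)
    fa = float(np.sqrt(1.5 * num / den)) if den > 0 else 0.0
    return md, ad, rd, fa


def delta_frobenius(dt: np.ndarray) -> float:
    """Squared Frobenius norm of D from the 6 unique elements."""
    dt = np.asarray(dt, dtype=float).reshape(6)
    return float(np.sum(dt[:3] ** 2) + 2.0 * np.sum(dt[3:] ** 2))


def psi_correction(dt: np.ndarray) -> float:
    """Anisotropy correction term for the powder kurtosis.

    ``Psi = (2/5) * delta / Dbar^2 - 6/5`` with ``delta = ||D||_F^2``.
    Zero for isotropic D, positive otherwise; a rotational invariant.
    """
    dt = np.asarray(dt, dtype=float).reshape(6)
    md = np.sum(dt[:3]) / 3.0
    if md <= 0:
        raise ValueError("mean diffusivity must be positive")
    return 0.4 * delta_frobenius(dt) / (md * md) - 1.2
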