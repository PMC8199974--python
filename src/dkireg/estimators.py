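"""Voxelwise tensor estimators: ordinary, smoothed, constrained and
regularized nonlinear least squares.

All estimators minimize the amplitude-space misfit ``||S - exp(B theta)||^2``
over the 22-parameter vector theta (log amplitude, diffusion block, extended
kurtosis block).  The regularized estimator adds an L2 penalty pulling the
closed-form tensor mean kurtosis toward an externally supplied robust
prediction ``K_hat``:

    theta_hat = argmin ||S - exp(B theta)||^2 + alpha * (MKT(theta) - K_hat)^2

For ``alpha = 0`` this reduces exactly to the ordinary estimator.  The
regularized fit starts from the ordinary solution; if that stage ends in an
implausible voxel (non-positive or extreme mean kurtosis, out-of-range mean
diffusivity, or non-convergence) it is restarted from the constrained
solution, which enforces non-negative apparent kurtosis along every
acquired direction.

Signals are normalized by the voxel's mean b=0 amplitude before fitting so
that the default regularization weight has a fixed meaning across voxels;
the normalization is undone in the reported log amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d
from scipy.optimize import least_squares, minimize

from .tensor_model import (DKIParams, GradientScheme, build_design_matrix,
                           dti_metrics, mean_kurtosis_directional,
                           mkt_from_theta, mkt_theta_gradient, _kt_monomials)

__all__ = ["FitResult", "fit_ordinary_nls", "fit_constrained_nls",
           "fit_regularized_nls", "smooth_then_fit", "plausibility_check",
           "fit_volume", "PlausibilityWindow"]

DEFAULT_ALPHA = 0.1
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


@dataclass(frozen=True)
class PlausibilityWindow:
    """Acceptance window for a fitted voxel (configurable defaults)."""

    mk_min: float = 0.0
    mk_max: float = 10.0
    md_min: float = 0.0
    md_max: float = 4.0   # um^2/ms


@dataclass
class FitResult:
    params: DKIParams
    converged: bool
    n_iter: int
    restarted: bool = False
    plausible: bool = True
    residual_norm: float = np.nan   # squared data misfit on normalized signals
    penalty_value: float = 0.0      # alpha * (MKT - K_hat)^2 at the solution
    at_bound: bool = False          # any positivity constraint active
    mk: float = field(default=np.nan)  # reported directional mean kurtosis


def _normalize(signals: np.ndarray, scheme: GradientScheme):
    s0 = float(np.mean(signals[scheme.b0_mask]))
    if not np.isfinite(s0) or s0 <= 0:
        raise ValueError("non-positive mean b=0 signal")
    return signals / s0, np.log(s0)


def _wlls_start(signals: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Weighted log-linear start: weights ~ signal amplitude."""
    floor = max(1e-6, 1e-6 * float(np.max(signals)))
    s = np.maximum(signals, floor)
    w = s  # std of log S scales as 1/S under additive noise
    theta, *_ = np.linalg.lstsq(design * w[:, None], np.log(s) * w,
                                rcond=None)
    return theta


def _nls_core(signals, design, x0, extra_resid=None, extra_jac=None,
              max_iter: int = 1000):
    """Trust-region NLS on amplitude residuals, optional penalty rows."""

    def resid(theta):
        r = np.exp(design @ theta) - signals
        if extra_resid is not None:
            r = np.append(r, extra_resid(theta))
        return r

    def jac(theta):
        model = np.exp(design @ theta)
        j = model[:, None] * design
        if extra_jac is not None:
            j = np.vstack([j, extra_jac(theta)])
        return j

    sol = least_squares(resid, x0, jac=jac, method="trf",
                        xtol=1e-10, ftol=1e-10, gtol=1e-10,
                        max_nfev=max_iter)
    return sol


def _finish(sol, log_s0_shift, scheme, window, n_dirs_mk,
            restarted=False, penalty=0.0, at_bound=False) -> FitResult:
    theta = sol.x.copy()
    converged = bool(sol.status > 0 and np.all(np.isfinite(theta)))
    params = DKIParams.from_theta(theta)
    params.log_s0 += log_s0_shift
    mk = mean_kurtosis_directional(params, n_dirs_mk) if converged else np.nan
    res = FitResult(params=params, converged=converged,
                    n_iter=int(sol.nfev), restarted=restarted,
                    residual_norm=float(2.0 * sol.cost) - penalty,
                    penalty_value=penalty, at_bound=at_bound, mk=mk)
    res.plausible = plausibility_check(res, window)
    return res


def plausibility_check(result: FitResult,
                       window: PlausibilityWindow = PlausibilityWindow()
                       ) -> bool:
    """A voxel is plausible iff it converged with mean kurtosis and mean
    diffusivity inside the window (negative kurtosis is the canonical
    failure mode)."""
    if not result.converged or not np.isfinite(result.mk):
        return False
    md = result.params.md
    return (window.mk_min < result.mk < window.mk_max
            and window.md_min < md < window.md_max)


def fit_ordinary_nls(signals: np.ndarray, scheme: GradientScheme,
                     design: np.ndarray | None = None,
                     window: PlausibilityWindow = PlausibilityWindow(),
                     n_dirs_mk: int = 100) -> FitResult:
    """Unconstrained NLS fit of one voxel, seeded by weighted log-linear LS."""
    signals = np.asarray(signals, dtype=float).reshape(-1)
    if not np.all(np.isfinite(signals)) or np.all(signals == 0):
        raise ValueError("voxel signals are all-zero or non-finite")
    if design is None:
        design = build_design_matrix(scheme)
    s, shift = _normalize(signals, scheme)
    x0 = _wlls_start(s, design)
    sol = _nls_core(s, design, x0)
    return _finish(sol, shift, scheme, window, n_dirs_mk)


def fit_constrained_nls(signals: np.ndarray, scheme: GradientScheme,
                        design: np.ndarray | None = None,
                        window: PlausibilityWindow = PlausibilityWindow(),
                        n_dirs_mk: int = 100,
                        constraint_tol: float = 1e-9) -> FitResult:
    """NLS subject to non-negative apparent kurtosis per acquired direction.

    In the extended b-matrix parameterization the sign of K_app(g) equals
    the sign of the fourth-order monomial contraction of the kurtosis
    block, so the constraints are linear in theta and are handled by
    sequential least-squares programming with fixed constraint matrix.
    """
    signals = np.asarray(signals, dtype=float).reshape(-1)
    if design is None:
        design = build_design_matrix(scheme)
    s, shift = _normalize(signals, scheme)
    dw = scheme.dw_mask
    cmat = np.zeros((int(dw.sum()), 22))
    cmat[:, 7:] = _kt_monomials(scheme.bvecs[dw])

    def objective(theta):
        r = np.exp(design @ theta) - s
        return float(r @ r)

    def gradient(theta):
        model = np.exp(design @ theta)
        return 2.0 * design.T @ (model * (model - s))

    x0 = _wlls_start(s, design)
    if np.any(cmat @ x0 < 0):
        x0 = x0.copy()
        x0[7:] = 0.0  # feasible fallback: zero kurtosis block
    sol = minimize(objective, x0, jac=gradient, method="SLSQP",
                   constraints=[{"type": "ineq",
                                 "fun": lambda t: cmat @ t + constraint_tol,
                                 "jac": lambda t: cmat}],
                   options={"maxiter": 500, "ftol": 1e-12})

    theta = sol.x
    at_bound = bool(np.any(cmat @ theta < 1e-6))
    params = DKIParams.from_theta(theta)
    params.log_s0 += shift
    converged = bool(sol.success or sol.status == 0)
    mk = mean_kurtosis_directional(params, n_dirs_mk) if converged else np.nan
    res = FitResult(params=params, converged=converged, n_iter=int(sol.nit),
                    residual_norm=float(sol.fun), at_bound=at_bound, mk=mk)
    res.plausible = plausibility_check(res, window)
    return res


def fit_regularized_nls(signals: np.ndarray, scheme: GradientScheme,
                        k_hat: float, alpha: float = DEFAULT_ALPHA,
                        design: np.ndarray | None = None,
                        window: PlausibilityWindow = PlausibilityWindow(),
                        n_dirs_mk: int = 100,
                        start: FitResult | None = None,
                        constrained_start: FitResult | None = None
                        ) -> FitResult:
    """Two-stage regularized NLS fit of one voxel.

    Stage 1 starts from the ordinary solution (``start`` if already
    computed).  If the stage-1 voxel is implausible or unconverged, stage 2
    restarts from the constrained solution and flags ``restarted``.  If both
    stages fail the plausibility check the better-objective result is
    returned with ``plausible=False``.

    A non-finite ``k_hat`` disables the penalty (falls back to the ordinary
    estimator for this voxel).
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    signals = np.asarray(signals, dtype=float).reshape(-1)
    if design is None:
        design = build_design_matrix(scheme)
    if not np.isfinite(k_hat):
        return fit_ordinary_nls(signals, scheme, design=design,
                                window=window, n_dirs_mk=n_dirs_mk)
    s, shift = _normalize(signals, scheme)
    sq_alpha = np.sqrt(alpha)

    def extra_resid(theta):
        return sq_alpha * (mkt_from_theta(theta) - k_hat)

    def extra_jac(theta):
        return sq_alpha * mkt_theta_gradient(theta)[None, :]

    if start is not None:
        x0 = start.params.to_theta()
        x0[0] -= shift
    else:
        x0 = _nls_core(s, design, _wlls_start(s, design)).x

    sol = _nls_core(s, design, x0, extra_resid, extra_jac)
    pen = float(extra_resid(sol.x) ** 2)
    stage1 = _finish(sol, shift, scheme, window, n_dirs_mk, penalty=pen)
    if stage1.plausible:
        return stage1

    # Stage 2: restart from the constrained solution
    if constrained_start is None:
        constrained_start = fit_constrained_nls(
            signals, scheme, design=design, window=window,
            n_dirs_mk=n_dirs_mk)
    x0c = constrained_start.params.to_theta()
    x0c[0] -= shift
    if not np.all(np.isfinite(x0c)):
        return stage1
    sol2 = _nls_core(s, design, x0c, extra_resid, extra_jac)
    pen2 = float(extra_resid(sol2.x) ** 2)
    stage2 = _finish(sol2, shift, scheme, window, n_dirs_mk,
                     restarted=True, penalty=pen2)
    if stage2.plausible or sol2.cost <= sol.cost:
        return stage2
    return stage1


def _gaussian_taps(sigma: float, half: int = 2) -> np.ndarray:
    """Discrete Gaussian kernel truncated to 2*half+1 taps, normalized."""
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def smooth_volumes(volumes: np.ndarray, fwhm_factor: float = 1.25
                   ) -> np.ndarray:
    """Per-slice 2D Gaussian smoothing of a 4D (x, y, z, volume) array.

    FWHM = ``fwhm_factor`` voxels in-plane; sigma = FWHM / (2 sqrt(2 ln 2));
    kernel truncated to 5x5 taps and renormalized.
    """
    if volumes.ndim != 4:
        raise ValueError("expected a 4D (x, y, z, volumes) array")
    if volumes.shape[0] < 5 or volumes.shape[1] < 5:
        raise ValueError("in-plane extent must be at least 5 voxels")
    taps = _gaussian_taps(fwhm_factor / _FWHM_TO_SIGMA)
    out = convolve1d(volumes, taps, axis=0, mode="nearest")
    return convolve1d(out, taps, axis=1, mode="nearest")


def smooth_then_fit(volumes: np.ndarray, scheme: GradientScheme,
                    fwhm_factor: float = 1.25, mask: np.ndarray | None = None,
                    **kwargs):
    """Gaussian-smooth the data in-plane, then ordinary NLS everywhere."""
    smoothed = smooth_volumes(volumes, fwhm_factor)
    return fit_volume(smoothed, scheme, estimator="ordinary", mask=mask,
                      **kwargs)


def fit_volume(volumes: np.ndarray, scheme: GradientScheme,
               estimator: str = "ordinary", mask: np.ndarray | None = None,
               k_hat: np.ndarray | None = None, alpha: float = DEFAULT_ALPHA,
               window: PlausibilityWindow = PlausibilityWindow(),
               n_dirs_mk: int = 100) -> np.ndarray:
    """Apply a voxelwise estimator over a 4D volume (or 2D voxel table).

    Returns an object array of :class:`FitResult` (None outside the mask),
    shaped like the spatial grid.  Voxels are processed in ascending flat
    order, so output is independent of any chunking.
    """
    vols = np.asarray(volumes, dtype=float)
    spatial = vols.shape[:-1]
    flat = vols.reshape(-1, vols.shape[-1])
    if mask is None:
        mask_flat = np.ones(flat.shape[0], dtype=bool)
    else:
        mask_flat = np.asarray(mask, dtype=bool).reshape(-1)
    design = build_design_matrix(scheme)
    khf = (np.asarray(k_hat, dtype=float).reshape(-1)
           if k_hat is not None else None)

    results = np.empty(flat.shape[0], dtype=object)
    for i in range(flat.shape[0]):
        if not mask_flat[i]:
            continue
        sig = flat[i]
        try:
            if estimator == "ordinary":
                results[i] = fit_ordinary_nls(
                    sig, scheme, design=design, window=window,
                    n_dirs_mk=n_dirs_mk)
            elif estimator == "constrained":
                results[i] = fit_constrained_nls(
                    sig, scheme, design=design, window=window,
                    n_dirs_mk=n_dirs_mk)
            elif estimator == "regularized":
                if khf is None:
                    raise ValueError(
                        "regularized estimator needs a k_hat map")
                results[i] = fit_regularized_nls(
                    sig, scheme, k_hat=float(khf[i]), alpha=alpha,
                    design=design, window=window, n_dirs_mk=n_dirs_mk)
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
        except ValueError as err:
            if "unknown estimator" in str(err) or "k_hat" in str(err):
                raise
            results[i] = None  # unusable voxel, flagged by absence
    return results.reshape(spatial)


def scalar_map(results: np.ndarray, func) -> np.ndarray:
    """Evaluate ``func(FitResult) -> float`` over a result grid (nan gaps)."""
    flat = results.reshape(-1)
    out = np.full(flat.shape, np.nan)
    for i, r in enumerate(flat):
        if r is not None:
            out[i] = func(r)
    return out.reshape(results.shape)
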