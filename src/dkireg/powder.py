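"""Powder-averaged (spherical-mean) signals and the scalar cumulant fit.

Averaging the diffusion-weighted signal over isotropically distributed
gradient directions within each shell removes the dependence on fiber
orientation.  The decay of these powder means with b is itself fitted with
a cumulant expansion,

    log Sdot(b) = log S0 - b * Ddot + (b^2 / 6) * Ddot^2 * Kdot,

yielding the powder diffusivity ``Ddot`` and powder kurtosis ``Kdot``.
Because each shell mean pools many directions, ``Kdot`` is far more precise
than tensor-derived kurtosis metrics and anchors the mean-kurtosis
predictors in :mod:`dkireg.mk_predict`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["PowderSummary", "group_shells", "powder_average",
           "fit_powder_cumulants"]


@dataclass
class PowderSummary:
    """Scalar cumulant fit of the powder-averaged decay of one voxel."""

    s0_dot: float          # fitted b=0 powder amplitude, a.u.
    d_dot: float           # powder diffusivity, um^2/ms
    k_dot: float           # powder kurtosis, dimensionless
    shell_means: np.ndarray
    fit_ok: bool


def group_shells(bvals, tol: float = 0.05) -> np.ndarray:
    """Cluster volumes into b-value shells; returns an integer label array.

    Volumes whose b-values lie within ``tol`` (ms/um^2) of a running
    cluster mean share a shell; b=0 is always its own shell.  Labels are
    ordered by ascending shell b-value.
    """
    bvals = np.atleast_1d(np.asarray(
        getattr(bvals, "bvals", bvals), dtype=float))
    if bvals.size == 0:
        raise ValueError("empty gradient scheme")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    order = np.argsort(bvals, kind="stable")
    labels = np.empty(bvals.size, dtype=int)
    current = -1
    cluster: list[int] = []
    for idx in order:
        b = bvals[idx]
        if cluster and (b - bvals[cluster[0]] <= tol) and not (
                b > 0 and bvals[cluster[0]] == 0):
            cluster.append(idx)
        else:
            current += 1
            cluster = [idx]
        labels[idx] = current
    # shells closer together than tol indicate a smeared b-value cluster
    means = shell_bvalues(bvals, labels)
    gaps = np.diff(means)
    if np.any((gaps <= tol) & (means[1:] > 0)):
        raise ValueError(
            "b-value cluster spans more than the grouping tolerance; "
            "increase tol")
    return labels


def shell_bvalues(bvals: np.ndarray, shell_ids: np.ndarray) -> np.ndarray:
    """Within-shell mean b-value per shell label (ascending label order)."""
    return np.array([np.mean(bvals[shell_ids == s])
                     for s in np.unique(shell_ids)])


def powder_average(signals: np.ndarray, shell_ids: np.ndarray) -> np.ndarray:
    """Arithmetic mean of signals per shell.

    ``signals`` may be 1-D (one voxel) or 2-D ``(n_voxels, n_volumes)``.
    Non-finite entries are excluded from the mean; a shell with no finite
    entry yields nan for that voxel.
    """
    signals = np.asarray(signals, dtype=float)
    squeeze = signals.ndim == 1
    sig = np.atleast_2d(signals)
    shells = np.unique(shell_ids)
    out = np.empty((sig.shape[0], shells.size))
    for col, s in enumerate(shells):
        block = sig[:, shell_ids == s]
        finite = np.isfinite(block)
        with np.errstate(invalid="ignore"):
            out[:, col] = np.where(
                finite.any(axis=1),
                np.nansum(np.where(finite, block, 0.0), axis=1)
                / np.maximum(finite.sum(axis=1), 1),
                np.nan)
    return out[0] if squeeze else out


def _exact_three_shell(log_means: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact (log_s0, d, k) through three shell means: a linear solve in
    (log_s0, d, d^2 k / 6) followed by back-substitution."""
    design = np.column_stack([np.ones_like(b), -b, b * b])
    c = np.linalg.solve(design, log_means)
    d = max(c[1], 1e-8)
    return np.array([c[0], d, 6.0 * c[2] / (d * d)])


def fit_powder_cumulants(shell_means: np.ndarray,
                         shell_bvals: np.ndarray) -> PowderSummary:
    """Fit the scalar cumulant model to per-shell powder means of one voxel.

    Nonlinear least squares on log shell means with ``d_dot`` constrained
    positive.  With exactly 3 shells the exact closed-form solution seeds
    (and usually terminates) the fit; otherwise a quadratic log-linear
    solve seeds it.
    """
    shell_means = np.asarray(shell_means, dtype=float).reshape(-1)
    b = np.asarray(shell_bvals, dtype=float).reshape(-1)
    if shell_means.size != b.size:
        raise ValueError("shell means and b-values disagree")
    if b.size < 3:
        raise ValueError("need at least 3 shells (including b=0)")
    if np.any(~np.isfinite(shell_means)) or np.any(shell_means <= 0):
        return PowderSummary(np.nan, np.nan, np.nan, shell_means, False)
    y = np.log(shell_means)

    if b.size == 3:
        x0 = _exact_three_shell(y, b)
    else:
        design = np.column_stack([np.ones_like(b), -b, b * b])
        c, *_ = np.linalg.lstsq(design, y, rcond=None)
        d0 = max(c[1], 1e-3)
        x0 = np.array([c[0], d0, 6.0 * c[2] / (d0 * d0)])

    def resid(x):
        ls0, d, k = x
        return ls0 - b * d + (b * b / 6.0) * d * d * k - y

    def jac(x):
        _, d, k = x
        return np.column_stack([
            np.ones_like(b),
            -b + (b * b / 3.0) * d * k,
            (b * b / 6.0) * d * d,
        ])

    sol = least_squares(resid, x0, jac=jac,
                        bounds=([-np.inf, 1e-8, -np.inf],
                                [np.inf, np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    ok = bool(sol.status > 0 and np.all(np.isfinite(sol.x)))
    ls0, d, k = sol.x
    return PowderSummary(float(np.exp(ls0)), float(d), float(k),
                         shell_means, ok)


def powder_summaries(signals: np.ndarray, scheme) -> list[PowderSummary]:
    """Powder cumulant fit for every voxel row of a 2-D signal array."""
    from .tensor_model import GradientScheme  # typing only
    assert isinstance(scheme, GradientScheme)
    means = powder_average(np.atleast_2d(signals), scheme.shell_ids)
    bshell = shell_bvalues(scheme.bvals, scheme.shell_ids)
    return [fit_powder_cumulants(row, bshell) for row in means]
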