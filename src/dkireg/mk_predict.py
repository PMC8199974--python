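"""Robust mean-kurtosis prediction from powder cumulants.

Three strategies produce a per-voxel prediction ``K_hat`` of the mean
kurtosis without a (fragile) full kurtosis-tensor fit:

1. analytic:   ``K_hat = Kdot - Psi(D)`` — exact in the b -> 0 limit,
   with ``Psi`` the diffusion-anisotropy correction term;
2. powder:     ``K_hat = Kdot`` — the powder kurtosis itself (exact for
   isotropic diffusion);
3. polynomial *voxel quality transfer* — a multivariate polynomial in
   ``(Kdot, Dbar, delta)`` (powder kurtosis, mean diffusivity, squared
   Frobenius norm of D) trained on the non-problematic voxels of the same
   acquisition, with ordinary-NLS mean kurtosis as the target.

Strategy 3 is the default.  Because tensor metrics depend strongly on the
acquisition (b-values, direction count), a trained model stores a scheme
fingerprint and refuses to predict on a protocol whose b-values differ by
more than 5%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .tensor_model import (GradientScheme, delta_frobenius, psi_correction,
                           _kt_monomials)

__all__ = ["PolynomialModel", "predict_mk_analytic", "predict_mk_powder",
           "select_training_voxels", "train_polynomial",
           "predict_mk_polynomial", "monomial_exponents"]


def monomial_exponents(order: int, n_vars: int = 3) -> list[tuple[int, ...]]:
    """All exponent tuples of total degree <= order (graded lexicographic).

    For 3 predictors and order N there are C(N+3, 3) of them (20 at N=3).
    """
    out = []
    for total in range(order + 1):
        for i in range(total + 1):
            for j in range(total - i + 1):
                out.append((i, j, total - i - j))
    return out


@dataclass
class PolynomialModel:
    """Voxel-quality-transfer regression of order N in (Kdot, Dbar, delta)."""

    order: int
    exponents: list
    coeffs: np.ndarray
    center: np.ndarray      # per-predictor mean used for standardization
    scale: np.ndarray       # per-predictor SD
    n_train: int
    scheme_fingerprint: dict | None = None

    def to_json(self, path):
        payload = {
            "order": self.order,
            "exponents": [list(e) for e in self.exponents],
            "coeffs": self.coeffs.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "n_train": self.n_train,
            "scheme_fingerprint": self.scheme_fingerprint,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PolynomialModel":
        with open(path) as fh:
            p = json.load(fh)
        return cls(order=p["order"],
                   exponents=[tuple(e) for e in p["exponents"]],
                   coeffs=np.asarray(p["coeffs"], dtype=float),
                   center=np.asarray(p["center"], dtype=float),
                   scale=np.asarray(p["scale"], dtype=float),
                   n_train=p["n_train"],
                   scheme_fingerprint=p.get("scheme_fingerprint"))

    def compatible_with(self, scheme: GradientScheme,
                        rel_tol: float = 0.05) -> bool:
        """True if the scheme's shell b-values match training within 5%."""
        if self.scheme_fingerprint is None:
            return True
        ref = sorted(s["b"] for s in
                     self.scheme_fingerprint["shells"].values())
        new = sorted(s["b"] for s in scheme.fingerprint()["shells"].values())
        if len(ref) != len(new):
            return False
        for a, b in zip(ref, new):
            if abs(a - b) > rel_tol * max(a, 1e-6):
                return False
        return True


def predict_mk_analytic(k_dot, dt) -> float | np.ndarray:
    """Strategy 1: powder kurtosis minus the anisotropy correction Psi."""
    k_dot = np.asarray(k_dot, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if dt.ndim == 1:
        return float(k_dot - psi_correction(dt))
    psi = np.array([psi_correction(row) for row in dt])
    return k_dot - psi


def predict_mk_powder(k_dot):
    """Strategy 2: the powder kurtosis itself (shape-preserving identity)."""
    return np.asarray(k_dot, dtype=float) + 0.0 if np.ndim(k_dot) else \
        float(k_dot)


def select_training_voxels(fit_results, scheme: GradientScheme,
                           k_dot=None) -> np.ndarray:
    """Mask of non-problematic voxels suitable for regression training.

    A voxel qualifies when its ordinary fit converged, its apparent
    kurtosis is positive along *every* acquired diffusion-weighted
    direction, its mean diffusivity is positive, and (when supplied) its
    powder kurtosis is finite.
    """
    flat = np.asarray(fit_results, dtype=object).reshape(-1)
    kmono = _kt_monomials(scheme.bvecs[scheme.dw_mask])
    mask = np.zeros(flat.shape[0], dtype=bool)
    for i, res in enumerate(flat):
        if res is None or not res.converged:
            continue
        p = res.params
        if not (np.all(np.isfinite(p.dt)) and np.all(np.isfinite(p.kt))):
            continue
        if p.md <= 0:
            continue
        # sign of K_app(g) equals sign of the kurtosis-block contraction
        if np.any(kmono @ p.kt <= 0):
            continue
        mask[i] = True
    if k_dot is not None:
        mask &= np.isfinite(np.asarray(k_dot, dtype=float).reshape(-1))
    return mask


def _design(predictors: np.ndarray, exponents, center, scale) -> np.ndarray:
    z = (predictors - center) / scale
    cols = [np.prod(z ** np.asarray(e, dtype=float), axis=1)
            for e in exponents]
    return np.column_stack(cols)


def train_polynomial(predictors: np.ndarray, targets: np.ndarray,
                     order: int = 3,
                     scheme: GradientScheme | None = None) -> PolynomialModel:
    """Ordinary least squares over all total-degree <= N monomials.

    ``predictors``: (n, 3) array of (Kdot, Dbar, delta) for training voxels;
    ``targets``: ordinary-NLS mean kurtosis of the same voxels.  Predictors
    are standardized before monomial expansion to keep the cubic design
    well conditioned; the affine constants are stored in the model.
    """
    predictors = np.asarray(predictors, dtype=float).reshape(-1, 3)
    targets = np.asarray(targets, dtype=float).reshape(-1)
    if order < 1:
        raise ValueError("order must be >= 1")
    exps = monomial_exponents(order)
    if predictors.shape[0] <= len(exps):
        raise ValueError(
            f"need more than {len(exps)} training voxels, got "
            f"{predictors.shape[0]}")
    finite = np.all(np.isfinite(predictors), axis=1) & np.isfinite(targets)
    predictors, targets = predictors[finite], targets[finite]
    center = predictors.mean(axis=0)
    scale = predictors.std(axis=0)
    scale[scale == 0] = 1.0
    design = _design(predictors, exps, center, scale)
    coeffs, _, rank, sv = np.linalg.lstsq(design, targets, rcond=None)
    if rank < len(exps):
        raise ValueError(
            f"rank-deficient polynomial design (rank {rank}/{len(exps)}, "
            f"condition number {sv[0] / max(sv[-1], 1e-300):.3g})")
    return PolynomialModel(order=order, exponents=exps, coeffs=coeffs,
                           center=center, scale=scale,
                           n_train=int(predictors.shape[0]),
                           scheme_fingerprint=(scheme.fingerprint()
                                               if scheme else None))


def predict_mk_polynomial(model: PolynomialModel, k_dot, md, delta
                          ) -> np.ndarray:
    """Strategy 3 (default): evaluate the trained polynomial per voxel."""
    if model.coeffs is None or len(model.coeffs) == 0:
        raise ValueError("polynomial model is untrained")
    pred = np.column_stack([np.atleast_1d(np.asarray(k_dot, dtype=float)),
                            np.atleast_1d(np.asarray(md, dtype=float)),
                            np.atleast_1d(np.asarray(delta, dtype=float))])
    out = _design(pred, model.exponents, model.center, model.scale) \
        @ model.coeffs
    return float(out[0]) if np.ndim(k_dot) == 0 else out


def predictor_table(fit_results, powder_fits) -> np.ndarray:
    """(n, 3) predictor array (Kdot, Dbar, delta) from fit + powder lists."""
    flat = np.asarray(fit_results, dtype=object).reshape(-1)
    out = np.full((flat.shape[0], 3), np.nan)
    for i, (res, pw) in enumerate(zip(flat, powder_fits)):
        if res is None or pw is None:
            continue
        out[i, 0] = pw.k_dot if pw.fit_ok else np.nan
        out[i, 1] = res.params.md
        out[i, 2] = delta_frobenius(res.params.dt)
    return out
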