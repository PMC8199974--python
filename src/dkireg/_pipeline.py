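"""End-to-end voxel-table workflows shared by the CLI and scripts.

Operates on flat ``(n_voxels, n_volumes)`` signal tables; spatial callers
reshape around these.
"""

from __future__ import annotations

import numpy as np

from .estimators import (DEFAULT_ALPHA, PlausibilityWindow,
                         fit_ordinary_nls, fit_regularized_nls)
from .mk_predict import (PolynomialModel, predict_mk_analytic,
                         predict_mk_polynomial, predict_mk_powder,
                         predictor_table, select_training_voxels,
                         train_polynomial)
from .powder import powder_summaries
from .tensor_model import (GradientScheme, build_design_matrix,
                           mean_kurtosis_tensor)


def fit_ordinary_table(signals: np.ndarray, scheme: GradientScheme,
                       n_dirs_mk: int = 100) -> list:
    design = build_design_matrix(scheme)
    out = []
    for row in np.atleast_2d(signals):
        try:
            out.append(fit_ordinary_nls(row, scheme, design=design,
                                        n_dirs_mk=n_dirs_mk))
        except ValueError:
            out.append(None)
    return out


def predict_khat(signals: np.ndarray, scheme: GradientScheme,
                 strategy: int = 3, order: int = 3,
                 model: PolynomialModel | None = None,
                 ordinary_fits: list | None = None,
                 train_mask: np.ndarray | None = None,
                 n_dirs_mk: int = 100,
                 khat_window: tuple = (0.0, 10.0),
                 target_metric: str = "mk"):
    """Per-voxel robust mean-kurtosis prediction by the chosen strategy.

    Returns ``(k_hat, model, ordinary_fits, powder_fits)``.  Strategy 3
    trains the voxel-quality-transfer polynomial on the non-problematic
    voxels (optionally restricted by ``train_mask``) unless a pre-trained
    ``model`` is given.  Polynomial predictions outside ``khat_window``
    (voxels whose predictors lie far outside the training cloud, where a
    cubic extrapolates without control) are set to nan, which downstream
    disables the regularization for those voxels.

    ``target_metric`` selects the regression target for strategy 3:
    ``"mk"`` (default) trains on the directional mean kurtosis — the
    reported metric — while ``"mkt"`` trains on the closed-form tensor
    mean.  The latter is the quantity the regularization penalty acts on,
    so penalty-bound predictions use it to keep the prior on the same
    scale as the penalized operator.
    """
    signals = np.atleast_2d(signals)
    powder_fits = powder_summaries(signals, scheme)
    k_dot = np.array([p.k_dot if p.fit_ok else np.nan for p in powder_fits])
    if strategy == 2:
        return predict_mk_powder(k_dot), None, ordinary_fits, powder_fits
    if ordinary_fits is None:
        ordinary_fits = fit_ordinary_table(signals, scheme, n_dirs_mk)
    pred = predictor_table(ordinary_fits, powder_fits)
    if strategy == 1:
        khat = np.full(signals.shape[0], np.nan)
        ok = np.all(np.isfinite(pred), axis=1)
        khat[ok] = predict_mk_analytic(
            k_dot[ok], np.array([ordinary_fits[i].params.dt
                                 for i in np.flatnonzero(ok)]))
        return khat, None, ordinary_fits, powder_fits
    if strategy != 3:
        raise ValueError("strategy must be 1, 2 or 3")
    if model is None:
        sel = select_training_voxels(np.array(ordinary_fits, dtype=object),
                                     scheme, k_dot=k_dot)
        if train_mask is not None:
            sel &= np.asarray(train_mask, dtype=bool).reshape(-1)
        if target_metric == "mk":
            targets = np.array([r.mk if r is not None else np.nan
                                for r in ordinary_fits])
        elif target_metric == "mkt":
            targets = np.array([mean_kurtosis_tensor(r.params)
                                if r is not None else np.nan
                                for r in ordinary_fits])
        else:
            raise ValueError("target_metric must be 'mk' or 'mkt'")
        sel &= np.isfinite(targets)
        model = train_polynomial(pred[sel], targets[sel], order=order,
                                 scheme=scheme)
    khat = np.full(signals.shape[0], np.nan)
    ok = np.all(np.isfinite(pred), axis=1)
    khat[ok] = predict_mk_polynomial(model, pred[ok, 0], pred[ok, 1],
                                     pred[ok, 2])
    khat[(khat <= khat_window[0]) | (khat >= khat_window[1])] = np.nan
    return khat, model, ordinary_fits, powder_fits


def fit_regularized_table(signals: np.ndarray, scheme: GradientScheme,
                          k_hat: np.ndarray, alpha: float = DEFAULT_ALPHA,
                          ordinary_fits: list | None = None,
                          window: PlausibilityWindow = PlausibilityWindow(),
                          n_dirs_mk: int = 100) -> list:
    signals = np.atleast_2d(signals)
    design = build_design_matrix(scheme)
    if ordinary_fits is None:
        ordinary_fits = fit_ordinary_table(signals, scheme, n_dirs_mk)
    out = []
    for i, row in enumerate(signals):
        start = ordinary_fits[i]
        try:
            out.append(fit_regularized_nls(
                row, scheme, k_hat=float(k_hat[i]), alpha=alpha,
                design=design, window=window, n_dirs_mk=n_dirs_mk,
                start=start if (start is not None and start.converged)
                else None))
        except ValueError:
            out.append(None)
    return out
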