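# dkireg — robust diffusion kurtosis imaging

Diffusion kurtosis imaging (DKI) extends the diffusion tensor model with a
fourth-order kurtosis tensor **W** that quantifies non-Gaussian water
diffusion in tissue. Its headline metrics — mean kurtosis (K̄), radial
kurtosis (K⊥) and axial kurtosis (K∥) — are sensitive markers of
microstructure, but the 21-parameter fit is notoriously fragile: thermal
noise and small signal artifacts routinely produce physically impossible
*negative* kurtosis, the "black voxels" that blight kurtosis maps and
corrupt ROI statistics.

`dkireg` implements a regularized estimator that stabilizes the fit with a
prior the data itself provides. Powder-averaging the signal over the
gradient directions of each b-shell gives a scalar decay

&nbsp;&nbsp;&nbsp;&nbsp;log S̄(b) = log S₀ − b·D̄̇ + (b²/6)·D̄̇²·K̇,

whose *powder kurtosis* K̇ is estimated far more precisely than any
tensor-derived metric (3 parameters, direction-averaged data). From K̇
and the diffusion tensor, a robust per-voxel prediction K̂ of the mean
kurtosis is built by one of three strategies:

1. **analytic** — K̂ = K̇ − Ψ, with Ψ = (2/5)·‖D‖²_F/D̄² − 6/5 the
   anisotropy correction (exact as b → 0);
2. **powder** — K̂ = K̇ (exact for isotropic diffusion);
3. **voxel quality transfer** (default) — an order-3 multivariate
   polynomial in (K̇, D̄, ‖D‖²_F), trained on the *non-problematic* voxels
   of the same acquisition (positive apparent kurtosis along every
   gradient direction) and applied everywhere.

The full tensor fit then minimizes

&nbsp;&nbsp;&nbsp;&nbsp;θ̂ = argmin_θ ‖S − exp(−Bθ)‖² + α·(h(θ) − K̂)²,

where B is the extended b-matrix, h the closed-form tensor mean kurtosis,
and α the regularization weight (default 0.1 on b0-normalized signals).
The fit starts from the ordinary nonlinear least-squares solution;
implausible voxels are refit from a constrained solution that enforces
non-negative apparent kurtosis. Ordinary, smoothed and constrained
estimators are included as comparators, along with evaluation statistics
(test–retest variability, percentage-error summaries, negative-kurtosis
fractions, PIS flags, χ² residual checks) and a Monte-Carlo simulation
module with analytically exact ground truth.

## Worked example

Fit a noisy three-region synthetic phantom (gray-matter-like mixture,
coherent fiber, 90° crossing; 95 volumes at b = 0, 0.5, 1, 2.5 ms/μm²,
SNR 20) with and without the regularization:

```python
import numpy as np
from dkireg import negative_fraction, percentage_error_summary
from dkireg.simulation import (NoiseModel, build_phantom, study_scheme,
                               tissue_regions)
from dkireg._pipeline import fit_regularized_table, predict_khat

scheme = study_scheme()
data, truth, labels = build_phantom(
    shape=(20, 10, 4), regions=tissue_regions(), scheme=scheme,
    noise=NoiseModel(snr=20, seed=0))
signals = data.reshape(-1, scheme.n_volumes)

k_hat, model, ordinary, _ = predict_khat(signals, scheme,
                                         target_metric="mkt")
regular = fit_regularized_table(signals, scheme, k_hat,
                                ordinary_fits=ordinary)

mk_ord = np.array([r.mk if r else np.nan for r in ordinary])
mk_reg = np.array([r.mk if r else np.nan for r in regular])
gt_mk = truth["mk"].reshape(-1)
print(f"negative-MK voxels, ordinary NLS:    {negative_fraction(mk_ord):.2f} %")
print(f"negative-MK voxels, regularized NLS: {negative_fraction(mk_reg):.2f} %")
print(f"ordinary-fit MK error:    {percentage_error_summary(mk_ord, gt_mk)[0]:+.2f} %")
print(f"regularized-fit MK error: {percentage_error_summary(mk_reg, gt_mk)[0]:+.2f} %")
```

prints

```
negative-MK voxels, ordinary NLS:    0.38 %
negative-MK voxels, regularized NLS: 0.00 %
ordinary-fit MK error:    -10.24 %
regularized-fit MK error: -1.60 %
```

The ordinary fit leaves a fraction of negative-kurtosis voxels and a
strong noise-driven underestimation of the mean kurtosis in the
low-radial-diffusivity fiber regions; the regularized fit removes the
negative voxels and pulls the bias close to zero.

The same pipeline is available from the shell for NIfTI + FSL bval/bvec
inputs:

```bash
dkireg simulate --out-prefix ph --shape 20,20,5 --snr 25 --seed 1
dkireg fit --dwi ph_dwi.nii.gz --bval ph.bval --bvec ph.bvec \
           --estimator regularized --out-prefix maps
```

which writes `maps_{mk,md,fa,ak,rk}.nii.gz`, flag maps (negative MK, PIS,
restarts) and a JSON provenance sidecar. `dkireg alpha-sweep` produces a
diagnostic of the negative-voxel fraction versus the regularization
weight.

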