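# Methods

## Signal representation

A voxel's diffusion-weighted signal is modeled by its second- and
fourth-order cumulants,

    log S(b, g) = log S0 − b Σ g_i g_j D_ij
                  + (b²/6) D̄² Σ g_i g_j g_k g_l W_ijkl,

with `b` in ms/μm², `g` a unit gradient direction, `D` the symmetric
diffusion tensor (μm²/ms, 6 unique elements), `W` the fully symmetric
kurtosis tensor (dimensionless, 15 unique elements) and `D̄ = tr(D)/3`.
The expansion is a truncation: it is accurate for brain tissue up to
b ≈ 2.5–3 ms/μm² and degrades beyond.

Internally the fitters use the extended b-matrix parameterization
`θ = (log S0, D_11..D_23, V_1111..V_1233)` with `V = D̄²·W`, which makes
the log-signal *linear* in all 22 parameters and the apparent-kurtosis
positivity constraints linear as well. Unique-element ordering is fixed
(documented in `tensor_model`); off-diagonal and mixed-index elements
carry their permutation multiplicities (2 for D; 4, 6, 12 for W) inside
the design matrix, so `log S = B θ` holds exactly.

Scalar metrics: MD/AD/RD/FA from the eigen-decomposition of D; the
reported mean kurtosis K̄ is the average of the apparent kurtosis
K_app(g) = (D̄²/D_app²)·W(g) over a deterministic 100-point Fibonacci
sphere (configurable, ≥ 45); the tensor mean kurtosis
MKT = (W1111 + W2222 + W3333 + 2W1122 + 2W1133 + 2W2233)/5 is the smooth
closed form used inside the regularization penalty; axial kurtosis is
K_app along the principal eigenvector of D and radial kurtosis the mean
over 64 directions in the perpendicular plane. Directions with
non-positive apparent diffusivity make the directional metrics undefined;
such voxels return NaN and a flag rather than raising mid-map.

## Powder cumulants

Signals are averaged per b-shell (shells grouped by a 0.05 ms/μm²
b-value tolerance; arithmetic mean; non-finite volumes excluded) and the
scalar model `log S̄(b) = log S0 − b D̄̇ + (b²/6) D̄̇² K̇` is fitted by
nonlinear least squares in log space with D̄̇ constrained positive. With
exactly three shells the exact closed-form solution seeds the fit; with
more shells a quadratic log-linear solve does. The b = 0 shell mean is a
data point, not a fixed intercept.

## Mean-kurtosis prediction

Three strategies produce the robust prediction K̂ (strategy 3 is the
default):

1. `K̂ = K̇ − Ψ`, `Ψ = (2/5)·δ/D̄² − 6/5`, `δ = ‖D‖²_F`. Exact in the
   b → 0 limit on the tensor-mean scale; at finite b it underestimates
   noticeably (the simulation shows ≈ −9 to −19% depending on the
   substrate pool).
2. `K̂ = K̇`. Nearly unbiased for low anisotropy, biased upward by ≈ Ψ
   for coherent fibers.
3. Voxel quality transfer: ordinary least squares over all monomials of
   total degree ≤ 3 in the standardized predictors (K̇, D̄, δ) — 20
   coefficients — trained on the non-problematic voxels (converged
   ordinary fit, K_app > 0 along every acquired direction, positive D̄,
   finite K̇) of the *same* acquisition. Predictors are standardized
   before the monomial expansion because raw cubic monomials in
   quantities of different magnitude are severely ill-conditioned; the
   affine constants are stored with the model, so serialization
   (JSON, with a scheme fingerprint) reproduces predictions bit-exactly.
   Models refuse to predict on schemes whose shell b-values differ by
   more than 5% from the training scheme — kurtosis metrics are strongly
   protocol-dependent.

Two regression targets exist. The *reported* K̂ is trained on the
ordinary-fit directional K̄ (it predicts the metric users look at). The
copy used inside the regularization penalty is trained on the
ordinary-fit MKT instead: the penalty operator h *is* the MKT, and the
directional K̄ sits systematically above the MKT for anisotropic voxels
(≈ 5–10% here), so penalizing MKT toward a K̄-scale target injects a
systematic upward push that the optimizer routes into the data-poor
axial direction. Training the penalty's prior on the penalized quantity
removes that scale mismatch; the analytic strategy-1 correction is
likewise derived on the tensor-mean scale. Polynomial predictions
falling outside (0, 10) — out-of-cloud extrapolation, e.g. pure free
water — are treated as missing, which disables the penalty for that
voxel.

## Estimators

All fits minimize amplitude-space residuals `‖S − exp(Bθ)‖²` on signals
normalized by the voxel's mean b = 0 amplitude (so α has a fixed meaning
across voxels). The ordinary fit starts from a weighted log-linear
solution (weights ∝ signal) and uses trust-region least squares with
analytic Jacobians (tolerances 1e-10, max 1000 evaluations).

The constrained fit imposes `K_app(g) ≥ 0` for every acquired
diffusion-weighted direction. In the V-parameterization these are fixed
linear constraints, handled by SLSQP with analytic gradients; a solution
with any constraint active within 1e-6 is flagged `at_bound` (constrained
solutions for genuinely corrupted voxels sit on the boundary almost
always).

The regularized fit adds the penalty row `√α·(MKT(θ) − K̂)` to the
residual vector. Stage 1 starts from the ordinary solution. If the
result is implausible — not converged, K̄ outside (0, 10), or MD outside
(0, 4) μm²/ms; windows configurable — stage 2 restarts from the
constrained solution and is flagged `restarted`. If both stages are
implausible the better-objective result is returned flagged. With α = 0
the estimator is the ordinary one (identical objective to 1e-12).
Non-finite K̂ disables the penalty for that voxel.

Default α = 0.1: on b0-normalized signals the expected residual term at
SNR 30 with 95 volumes is ≈ 95/30² ≈ 0.11, so a unit kurtosis deviation
costs about the full noise floor — strong enough to move outliers,
weak enough that well-fitted voxels barely move (measured mean shift of
non-problematic voxels ≈ 0.1 ± 0.8%). An `alpha-sweep` CLI diagnostic
plots the negative-voxel fraction against α.

The smoothed comparator applies a per-slice 2D Gaussian (FWHM = 1.25
voxels, σ = FWHM/(2√(2 ln 2)), kernel truncated to 5×5 taps and
renormalized) before ordinary fitting.

## Synthetic ground truth

Substrates are finite Gaussian mixtures, for which the cumulant tensors
are exact:

    D = Σ f_c D_c,    W = (3/D̄²)·sym(Σ f_c D_c⊗D_c − D⊗D).

The plausibility sampler emulates a whole-brain voxel pool: ~55%
gray-matter-like draws (axon fraction 0.05–0.35 of the tissue
compartment, near-uniform orientation dispersion) and ~45%
white-matter-like draws (axon fraction 0.4–0.8, dispersion σ 0.15–0.45
rad, 30% with a second fiber population crossing at 30–90°). Every draw
includes a free-water pool (volume fraction 0.05–0.25, D 1.5–3 μm²/ms)
and a small restricted pool (0.02–0.12, D 0.1–0.5), which keep the
apparent kurtosis bounded away from zero along every axis, as in tissue.
Fiber compartments pair an intra-axonal stick (AD 2–3, RD 0–0.2) with an
extra-axonal cylinder (AD 1–1.8, RD 0.5–1.2) sharing each
sub-orientation. Rejection sampling enforces MD ∈ [0.5, 3] μm²/ms,
FA ≤ 0.9, K̄ ∈ [0.2, 1.5] and strictly positive apparent kurtosis on a
60-direction check set. Resulting marginals: MD median ≈ 1.1, FA median
≈ 0.26 (5–95% 0.07–0.58), K̄ median ≈ 0.94, K∥ median ≈ 0.48, K⊥ median
≈ 1.3 — comparable to in-vivo whole-brain histograms.

Simulated signals evaluate the *cumulant representation* of the exact
mixture tensors (so estimator bias is measured free of truncation
error); a raw multi-exponential mode exists for robustness studies.
Noise is additive Gaussian with σ = S(b=0)/SNR, SNR 30 by default —
deliberately not Rician, so the Rician floor does not confound bias
readings. Consequences the generator does **not** emulate: magnitude
(Rician) bias, imaging artifacts (Gibbs ringing, motion, eddy currents,
signal voids), spatial noise correlations, and partial-volume geometry;
passing tests therefore demonstrate estimator behavior under thermal
noise, not artifact robustness.

The acquisition preset is 5 b=0 volumes plus 30 Fibonacci-sphere
directions at each of b = 0.5, 1, 2.5 ms/μm² (95 volumes); presets for
other protocols follow from `study_scheme(n_dirs=..., bvals=...)`.

The 3D phantom splits a grid into equal slabs per region. The default
layout is free water (MD 3, K = 0) / single fiber / 90° crossing. The
robustness comparisons use a tissue-only layout (isotropic gray-matter
mixture / fiber / crossing, all with K̄ > 0): under additive Gaussian
noise, a region with true K = 0 yields negative estimates for ~half its
voxels under *any* unbiased estimator, which measures sign flips rather
than estimator failure.

## Evaluation statistics

Test–retest variability: `TRV = c · mean(|t−r| / ((t+r)/2)) · 100` over
subjects. The scale c converting a mean absolute difference of Gaussian
pairs to a standard deviation is exactly √(π/2) ≈ 1.2533 (half-normal
mean identity), the default; a literal π/2 variant is selectable because
both conventions circulate. Values above 100% are reported as
outlier-dominated. The χ² goodness-of-fit check is two-sided on the
summed standardized squared residuals with n − 22 degrees of freedom at
5% — two-sided because an implausibly *good* fit is as diagnostic as a
bad one; residual counts near 95 are too small for stable binning, so
the unbinned sum is used. ROI summaries offer mean and median
aggregation (the median is robust to negative-voxel outliers).

## Problem sizes and numerical choices

The Monte-Carlo validation uses 2500 trials at SNR 30 (≈ 20 s on one
CPU); the robustness phantom 40×20×5 voxels at SNR 20, chosen mid-way in
the plausible clinical 15–30 band, with seeds fixed for bit
reproducibility. The polynomial train/evaluate split is even/odd voxel
index. Per-voxel fits are independent and processed in ascending flat
order, so results are identical under any chunking. Shell grouping
tolerance 0.05 ms/μm²; bval files with values > 50 are auto-converted
from s/mm²; bvecs are renormalized on load with a logged maximum
correction.

## Known limitations

- The penalty constrains the tensor mean; the *directional* K̄ weights
  low-diffusivity directions by (D̄/D_app)², so a rare voxel can keep a
  negative directional K̄ while its MKT sits exactly at the prior —
  increasing α does not help these, and they remain flagged implausible.
- Axial kurtosis in heavily corrupted voxels moves substantially when
  regularization rescues them (that is the point), so pooled
  axial-kurtosis bias summaries shift by a few points even though
  well-fitted voxels move < 2 points.
- Strategy-1/2 predictions inherit a finite-b truncation bias from the
  powder cumulant fit; only strategy 3 calibrates it away, and only
  within the acquisition it was trained on.
- The voxel-quality-transfer regression requires enough (> 20)
  non-problematic voxels in the acquisition; tiny or uniformly corrupted
  datasets cannot train it.
- No preprocessing is included or assumed (denoising, Gibbs, eddy,
  distortion, gradient-nonlinearity corrections are upstream concerns);
  bvecs are taken in the image frame without reorientation.
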