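"""Evaluation statistics for estimator comparisons.

Covers test-retest variability of ROI-averaged metrics, voxelwise
percentage-error summaries against a reference, the negative-kurtosis
fraction (the canonical robustness figure of merit), physically implausible
signal (PIS) flagging, and a Pearson chi-squared goodness-of-fit check on
fit residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["TRVReport", "trv", "percentage_error_summary",
           "negative_fraction", "flag_pis", "chi2_gof", "roi_means"]

#: half-normal mean-to-SD factor, sqrt(pi/2)
TRV_SCALE_HALF_NORMAL = float(np.sqrt(np.pi / 2.0))
TRV_SCALE_PI_OVER_2 = float(np.pi / 2.0)
_TRV_SCALES = {"half_normal": TRV_SCALE_HALF_NORMAL,
               "pi_over_2": TRV_SCALE_PI_OVER_2}

#: TRV above this is reported as outlier-dominated (table dash convention)
TRV_OUTLIER_LIMIT = 100.0


@dataclass
class TRVReport:
    """Per-ROI test-retest variability for one estimator."""

    per_roi: dict            # label -> TRV % (nan if outlier-dominated)
    n_subjects: int
    estimator_tag: str = ""
    outlier_dominated: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for roi, val in self.per_roi.items():
            rows.append({"roi": roi, "estimator": self.estimator_tag,
                         "trv_percent": val,
                         "outlier_dominated":
                         bool(self.outlier_dominated.get(roi, False))})
        return pd.DataFrame(rows)


def trv(test_values, retest_values, scale: str | float = "half_normal"
        ) -> float:
    """Test-retest variability (percent) across paired subject values.

    ``scale * mean(|test - retest| / ((test + retest)/2)) * 100`` with the
    scale converting a mean absolute difference of Gaussian pairs into a
    standard deviation.  Default scale sqrt(pi/2); the literal pi/2 variant
    is selectable.  Pairs whose average is zero are excluded.
    """
    t = np.asarray(test_values, dtype=float).reshape(-1)
    r = np.asarray(retest_values, dtype=float).reshape(-1)
    if t.size != r.size or t.size < 1:
        raise ValueError("test/retest must be equal-length and nonempty")
    factor = _TRV_SCALES[scale] if isinstance(scale, str) else float(scale)
    avg = (t + r) / 2.0
    good = np.isfinite(t) & np.isfinite(r) & (avg != 0)
    if not np.any(good):
        raise ValueError("no usable test/retest pairs")
    ratio = np.abs(t[good] - r[good]) / np.abs(avg[good])
    return float(factor * np.mean(ratio) * 100.0)


def trv_report(test_rois: dict, retest_rois: dict, estimator_tag: str = "",
               scale: str | float = "half_normal") -> TRVReport:
    """TRV per ROI label from {label: per-subject value arrays} dicts."""
    per_roi, dominated = {}, {}
    n_subj = 0
    for roi in test_rois:
        val = trv(test_rois[roi], retest_rois[roi], scale=scale)
        n_subj = max(n_subj, len(np.atleast_1d(test_rois[roi])))
        if val > TRV_OUTLIER_LIMIT:
            per_roi[roi] = np.nan
            dominated[roi] = True
        else:
            per_roi[roi] = val
            dominated[roi] = False
    return TRVReport(per_roi=per_roi, n_subjects=n_subj,
                     estimator_tag=estimator_tag,
                     outlier_dominated=dominated)


def percentage_error_summary(estimates, references
                             ) -> tuple[float, float, int]:
    """Voxelwise percentage error mean, SD and excluded-pair count.

    ``100 * (estimate - reference) / reference`` per voxel; non-finite
    pairs (or zero references) are excluded and counted.
    """
    est = np.asarray(estimates, dtype=float).reshape(-1)
    ref = np.asarray(references, dtype=float).reshape(-1)
    if est.size == 0 or est.size != ref.size:
        raise ValueError("need equal-length nonempty inputs")
    good = np.isfinite(est) & np.isfinite(ref) & (ref != 0)
    if not np.any(good):
        raise ValueError("no usable pairs")
    pe = 100.0 * (est[good] - ref[good]) / ref[good]
    return float(np.mean(pe)), float(np.std(pe)), int(np.sum(~good))


def negative_fraction(k_map, mask=None) -> float:
    """Percent of voxels with negative mean kurtosis inside the mask.

    Non-finite (flagged) voxels are excluded from numerator and
    denominator.
    """
    k = np.asarray(k_map, dtype=float).reshape(-1)
    m = (np.ones(k.size, dtype=bool) if mask is None
         else np.asarray(mask, dtype=bool).reshape(-1))
    if not np.any(m):
        raise ValueError("empty mask")
    vals = k[m]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return np.nan
    return float(100.0 * np.sum(vals < 0) / vals.size)


def flag_pis(signals, scheme) -> np.ndarray:
    """Physically-implausible-signal flag per voxel.

    True when any diffusion-weighted amplitude exceeds the voxel's mean
    b=0 amplitude.
    """
    sig = np.atleast_2d(np.asarray(signals, dtype=float))
    b0 = scheme.b0_mask
    if not np.any(b0):
        raise ValueError("scheme has no b=0 volume")
    mean_b0 = np.mean(sig[:, b0], axis=1)
    max_dw = np.max(sig[:, ~b0], axis=1)
    flags = max_dw > mean_b0
    return flags if np.asarray(signals).ndim > 1 else bool(flags[0])


def chi2_gof(residuals, sigma: float, n_params: int = 22,
             significance: float = 0.05) -> tuple[bool, float]:
    """Two-sided Pearson chi-squared residual check.

    Statistic ``sum((r / sigma)^2)`` against chi2 with ``n - n_params``
    degrees of freedom; fails in either tail at the given significance
    (an implausibly *good* fit fails too).  Returns (passed, p_value)
    where p_value is the two-sided tail probability.
    """
    if sigma is None or not np.isfinite(sigma) or sigma <= 0:
        raise ValueError(
            "noise standard deviation required; supply a noise-map estimate")
    r = np.asarray(residuals, dtype=float).reshape(-1)
    dof = r.size - n_params
    if dof < 1:
        raise ValueError("not enough residuals for the degrees of freedom")
    stat = float(np.sum((r / sigma) ** 2))
    cdf = stats.chi2.cdf(stat, dof)
    p_two = 2.0 * min(cdf, 1.0 - cdf)
    return bool(p_two >= significance), float(p_two)


def roi_means(value_map, labels, robust: bool = False) -> dict:
    """Mean (or median, ``robust=True``) of a metric per ROI label > 0."""
    v = np.asarray(value_map, dtype=float).reshape(-1)
    lab = np.asarray(labels).reshape(-1)
    out = {}
    for roi in np.unique(lab):
        if roi == 0:
            continue
        vals = v[lab == roi]
        vals = vals[np.isfinite(vals)]
        agg = np.median if robust else np.mean
        out[int(roi)] = float(agg(vals)) if vals.size else np.nan
    return out
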