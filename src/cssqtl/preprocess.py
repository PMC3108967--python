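"""Expression quality filtering, transformation and normalization.

The pipeline is detection filter (raw) -> variance-stabilizing log transform
(raw -> transformed) -> quantile normalization (transformed -> normalized),
with an advisory correlation-based sample outlier check.  The transform is a
log2(x + offset) surrogate for array-specific variance stabilization, and
quantile normalization stands in for spline-based distribution matching:
downstream mapping and network steps depend only on monotone, distribution-
matched values.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import ExpressionMatrix


def detection_filter(
    x: ExpressionMatrix,
    alpha: float = 0.01,
    min_detected_samples: int = 1,
) -> ExpressionMatrix:
    """Keep probes detected (p < alpha) in at least ``min_detected_samples`` samples.

    Sample set and probe order are preserved; retained/total counts are
    recorded in the result metadata.
    """
    x._require_stage("raw")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if min_detected_samples < 1:
        raise ValueError("min_detected_samples must be >= 1")
    if min_detected_samples > x.n_samples:
        raise ValueError(
            f"min_detected_samples={min_detected_samples} exceeds n_samples={x.n_samples}"
        )
    detected = (x.detection_p.to_numpy() < alpha).sum(axis=1)
    keep = detected >= min_detected_samples
    retained = [p for p, k in zip(x.probes, keep) if k]
    return x.subset_probes(
        retained,
        detection_filter={
            "alpha": alpha,
            "min_detected_samples": min_detected_samples,
            "retained": int(keep.sum()),
            "total": int(x.n_probes),
        },
    )


def vst_transform(x: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Variance-stabilizing transform ``y = log2(intensity + offset)``."""
    x._require_stage("raw")
    if offset <= 0:
        raise ValueError("offset must be positive")
    vals = x.intensities.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        raise ValueError("negative intensity encountered; expected raw intensities >= 0")
    out = pd.DataFrame(np.log2(vals + offset), index=x.intensities.index,
                       columns=x.intensities.columns)
    return x.replace_values(out, stage="transformed", vst_offset=offset)


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean empirical distribution.

    Each sample's sorted intensity vector is replaced by the across-sample
    mean of sorted vectors; ties within a sample receive the average of the
    reference values at their tied ranks.
    """
    x._require_stage("transformed", "normalized")
    vals = x.intensities.to_numpy(dtype=float)
    if x.n_samples == 1:
        warnings.warn("quantile_normalize with a single sample is an identity")
        return x.replace_values(x.intensities.copy(), stage="normalized")
    reference = np.sort(vals, axis=0).mean(axis=1)  # mean of sorted sample vectors
    out = np.empty_like(vals)
    grid = np.arange(1, vals.shape[0] + 1, dtype=float)
    for j in range(vals.shape[1]):
        ranks = rankdata(vals[:, j], method="average")  # ties -> average rank
        out[:, j] = np.interp(ranks, grid, reference)
    frame = pd.DataFrame(out, index=x.intensities.index, columns=x.intensities.columns)
    return x.replace_values(frame, stage="normalized")


def sample_outlier_flags(x: ExpressionMatrix, threshold: float = 3.0) -> pd.DataFrame:
    """Advisory outlier flags from mean inter-sample correlation.

    Sample i is flagged when its mean Pearson correlation with the other
    samples falls more than ``threshold`` SDs below the across-sample mean of
    that statistic.  Nothing is removed.
    """
    if x.n_samples < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    vals = x.intensities.to_numpy(dtype=float)
    corr = np.corrcoef(vals.T)
    np.fill_diagonal(corr, np.nan)
    mean_cor = np.nanmean(corr, axis=1)
    center, spread = mean_cor.mean(), mean_cor.std(ddof=1)
    if spread == 0 or not np.isfinite(threshold):
        flagged = np.zeros(x.n_samples, dtype=bool)
    else:
        flagged = mean_cor < center - threshold * spread
    return pd.DataFrame(
        {"mean_correlation": mean_cor, "flagged": flagged},
        index=pd.Index(x.samples, name="sample"),
    )


def preprocess(
    x: ExpressionMatrix,
    alpha: float = 0.01,
    min_detected_samples: int = 1,
    offset: float = 1.0,
) -> ExpressionMatrix:
    """Run filter -> transform -> normalize with one call."""
    return quantile_normalize(vst_transform(detection_filter(x, alpha, min_detected_samples), offset))
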