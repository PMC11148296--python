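"""First-order (histogram) statistics of the masked intensity sample.

Entropy and Uniformity are computed on the fixed-bin-width histogram
(same bin width as the GLCM discretization).  Kurtosis follows the Pearson
convention (a normal sample gives ~3).  Degenerate constant samples give
Variance 0, Entropy 0, Uniformity 1, Skewness 0, Kurtosis 3 — no NaNs.
"""

from __future__ import annotations

import numpy as np

from ..imaging_io import discretize_fixed_binwidth

__all__ = ["firstorder_features", "FIRSTORDER_FEATURE_NAMES"]

FIRSTORDER_FEATURE_NAMES = (
    "Mean", "Median", "Minimum", "Maximum", "Range", "Variance", "Skewness",
    "Kurtosis", "Energy", "TotalEnergy", "Entropy", "Uniformity",
    "RootMeanSquared", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "10Percentile", "90Percentile", "InterquartileRange",
)


def firstorder_features(values: np.ndarray, voxel_volume_mm3: float = 1.0,
                        bin_width: float = 5.0) -> dict[str, float]:
    """The 18-feature first-order set on a masked intensity sample."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 voxels")
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    sd = np.sqrt(var)
    centered = x - mean
    if sd > 0:
        skew = float((centered ** 3).mean() / sd ** 3)
        kurt = float((centered ** 4).mean() / sd ** 4)
    else:
        skew, kurt = 0.0, 3.0

    bins = discretize_fixed_binwidth(x, bin_width)
    p = np.bincount(bins)[1:].astype(np.float64)
    p = p[p > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    energy = float((x ** 2).sum())

    return {
        "Mean": float(mean),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": float(var),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume_mm3),
        "Entropy": entropy,
        "Uniformity": uniformity,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "MeanAbsoluteDeviation": float(np.abs(centered).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "InterquartileRange": float(p75 - p25),
    }
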