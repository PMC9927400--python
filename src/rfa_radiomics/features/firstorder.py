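"""First-order (intensity histogram) statistics over a masked region."""

from __future__ import annotations

import numpy as np


def firstorder_features(cube: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """Standard intensity statistics of in-mask voxels.

    Entropy and Uniformity are computed on an equal-width ``n_bins`` histogram
    over the in-mask range (log base 2); a constant region has entropy 0 and
    uniformity 1. Variance/skewness/kurtosis are population moments.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("firstorder_features: empty mask")
    v = np.asarray(cube, dtype=float)[mask]
    n = v.size
    mean = float(v.mean())
    var = float(v.var())
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(((v - mean) ** 3).mean() / sd**3)
        kurt = float(((v - mean) ** 4).mean() / sd**4)
    else:
        skew, kurt = 0.0, 0.0
    lo, hi = float(v.min()), float(v.max())
    if hi > lo:
        hist, _ = np.histogram(v, bins=n_bins, range=(lo, hi))
        p = hist / n
        nz = p > 0
        entropy = float(-(p[nz] * np.log2(p[nz])).sum())
        uniformity = float((p**2).sum())
    else:
        entropy, uniformity = 0.0, 1.0
    return {
        "Mean": mean,
        "Median": float(np.median(v)),
        "Minimum": lo,
        "Maximum": hi,
        "Range": hi - lo,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((v**2).sum()),
        "RootMeanSquared": float(np.sqrt((v**2).mean())),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "Entropy": entropy,
        "Uniformity": uniformity,
    }
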