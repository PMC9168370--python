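"""First-order (intensity histogram) features over pooled in-mask voxels."""

from __future__ import annotations

import numpy as np


def first_order_features(values: np.ndarray, voxel_volume: float = 1.0,
                         n_bins: int = 32) -> dict[str, float]:
    """The 18 first-order statistics of a 1-D array of in-mask intensities.

    Entropy and uniformity use an equal-width ``n_bins`` histogram over the
    in-mask min-max range.  Skewness/kurtosis of a zero-variance sample are
    0 by convention; kurtosis is the uncentred (Pearson) form.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty in-mask value set")
    n = x.size
    mean = float(x.mean())
    var = float(x.var())        # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    lo, hi = float(x.min()), float(x.max())
    if hi > lo:
        hist, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    else:
        hist = np.array([n])
    p = hist[hist > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    sub = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(sub - sub.mean()).mean()) if sub.size else 0.0
    if var > 0:
        m3 = float(((x - mean) ** 3).mean())
        m4 = float(((x - mean) ** 4).mean())
        skew = m3 / var ** 1.5
        kurt = m4 / var ** 2
    else:
        skew, kurt = 0.0, 0.0

    energy = float((x ** 2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": entropy,
        "Minimum": lo,
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": hi,
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": hi - lo,
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
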