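"""First-order (intensity histogram) features: the 18-feature IBSI set."""

from __future__ import annotations

import numpy as np

__all__ = ["FIRSTORDER_NAMES", "firstorder_features"]

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)

_EPS = 2.2e-16


def firstorder_features(values: np.ndarray,
                        levels: np.ndarray | None = None) -> dict[str, float]:
    """The 18 first-order features of a masked intensity sample.

    ``values`` are the (possibly z-scored) continuous intensities inside the
    ROI; ``levels`` are the discretized gray levels of the same pixels, used
    for Entropy and Uniformity (IBSI computes both on the discretized
    histogram).  When ``levels`` is omitted, values are binned at unit width.

    Moments use population (biased) estimators; Kurtosis is the plain fourth
    standardized moment (3.0 for a normal sample), not excess kurtosis.
    Skewness and Kurtosis of a constant sample are defined as 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("empty mask")
    if levels is None:
        levels = (np.floor(x - x.min()) + 1).astype(np.int64)
    levels = np.asarray(levels).ravel()

    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())

    mean = float(x.mean())
    var = float(x.var())  # population
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    if robust.size:
        rmad = float(np.abs(robust - robust.mean()).mean())
    else:
        rmad = 0.0
    if var > 0:
        sd = np.sqrt(var)
        skew = float(((x - mean) ** 3).mean() / sd ** 3)
        kurt = float(((x - mean) ** 4).mean() / var ** 2)
    else:
        skew, kurt = 0.0, 0.0

    energy = float((x ** 2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy,  # unit pixel area in 2D
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
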