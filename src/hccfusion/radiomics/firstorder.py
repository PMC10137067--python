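"""First-order intensity statistics (18 features).

Computed on raw intensities inside the VOI, except Entropy and Uniformity,
which use the fixed-bin-width discretized histogram.  Degenerate regions
follow the zero-variance convention: Skewness and Kurtosis of a constant
region are reported as 0 (and the event logged).
"""

from __future__ import annotations

import logging

import numpy as np

from .voi import DiscretizationParams, ImageVolume, VOIMask, discretize

logger = logging.getLogger(__name__)

FIRST_ORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order_features(
    volume: ImageVolume,
    mask: VOIMask,
    params: DiscretizationParams | None = None,
) -> dict[str, float]:
    """The 18 first-order statistics of the intensities inside ``mask``."""
    params = params or DiscretizationParams()
    mask.require_nonempty()
    x = volume.values[mask.indicator].astype(float)
    n = x.size
    mean = x.mean()
    var = x.var()  # population variance
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])

    if var > 0:
        sd = np.sqrt(var)
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / sd**4)
    else:
        logger.debug("constant region: skewness/kurtosis set to 0")
        skew = kurt = 0.0

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    levels = discretize(volume, mask, params)[mask.indicator]
    p = np.bincount(levels)[1:].astype(float)
    p = p[p > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    return {
        "Energy": float((x**2).sum()),
        "TotalEnergy": float(volume.voxel_volume * (x**2).sum()),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": float(var),
        "Uniformity": uniformity,
    }
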