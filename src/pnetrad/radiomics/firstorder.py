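"""First-order (histogram) intensity features."""

from __future__ import annotations

import numpy as np
from scipy import stats

from .preprocess import RoiSample

__all__ = ["first_order"]


def first_order(sample: RoiSample) -> dict[str, float]:
    """Intensity statistics over the resegmented ROI.

    Entropy is the Shannon entropy in bits of the discretized (fixed bin
    width) gray-level histogram; Energy is the raw sum of squared HU values
    and TotalEnergy scales it by the voxel volume in mm^3.
    """
    x = sample.intensities
    if x.size == 0:
        raise ValueError("empty ROI sample")
    voxel_volume = float(np.prod(sample.spacing))

    counts = np.bincount(sample.bins[sample.mask])[1:]
    p = counts[counts > 0] / counts.sum()
    entropy = float(-(p * np.log2(p)).sum())

    feats = {
        "Mean": float(np.mean(x)),
        "Median": float(np.median(x)),
        "Minimum": float(np.min(x)),
        "Maximum": float(np.max(x)),
        "Range": float(np.ptp(x)),
        "InterquartileRange": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "Energy": float(np.sum(x**2)),
        "TotalEnergy": float(voxel_volume * np.sum(x**2)),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Variance": float(np.var(x)),
        "Skewness": float(stats.skew(x)) if x.size > 1 and np.var(x) > 0 else 0.0,
        "Kurtosis": float(stats.kurtosis(x, fisher=False)) if x.size > 1 and np.var(x) > 0 else 0.0,
        "Entropy": entropy,
        "Uniformity": float(np.sum((counts / counts.sum()) ** 2)),
    }
    return feats
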