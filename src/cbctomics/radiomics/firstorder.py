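"""First-order (intensity histogram) features of an ROI.

All moments are population moments.  ``Entropy`` and ``Uniformity`` are
computed on the fixed-bin-width discretized histogram; ``Kurtosis`` is the
non-excess kurtosis (3.0 for a normal distribution).
"""
from __future__ import annotations

import numpy as np

from .discretize import discretize_array

__all__ = ["firstorder_features"]


def firstorder_features(
    data: np.ndarray,
    mask: np.ndarray,
    spacing,
    bin_width: float = 25.0,
) -> dict[str, float]:
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("first-order features require a nonempty mask")
    x = data[mask].astype(np.float64)
    n = x.size
    mean = x.mean()
    diff = x - mean
    m2 = float((diff**2).mean())
    m3 = float((diff**3).mean())
    m4 = float((diff**4).mean())
    sd = np.sqrt(m2)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    core = x[(x >= p10) & (x <= p90)]
    voxel_volume = float(np.prod(spacing))

    d = discretize_array(data, mask, bin_width)
    counts = np.bincount(d.labels[mask])[1:]
    p = counts[counts > 0] / n

    feats = {
        "Energy": float((x**2).sum()),
        "TotalEnergy": voxel_volume * float((x**2).sum()),
        "Entropy": float(-(p * np.log2(p)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(diff).mean()),
        "RobustMeanAbsoluteDeviation": float(np.abs(core - core.mean()).mean()),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": float(m3 / m2**1.5) if m2 > 0 else 0.0,
        "Kurtosis": float(m4 / m2**2) if m2 > 0 else 0.0,
        "Variance": m2,
        "Uniformity": float((p**2).sum()),
        "StandardDeviation": float(sd),
    }
    return feats
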