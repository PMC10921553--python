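"""Fixed-bin-width gray-level discretization of a region of interest."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..volumes import MaskVolume

__all__ = ["DiscretizedROI", "discretize", "discretize_array"]


@dataclass
class DiscretizedROI:
    """Integer gray levels (1..n_levels) on the ROI, 0 outside the mask."""

    labels: np.ndarray  # int32, full grid, 0 = outside ROI
    n_levels: int
    bin_width: float
    roi_min: float
    spacing: tuple[float, float, float]

    @property
    def roi_values(self) -> np.ndarray:
        return self.labels[self.labels > 0]


def discretize_array(
    data: np.ndarray, mask: np.ndarray, bin_width: float, spacing=(1.0, 1.0, 1.0)
) -> DiscretizedROI:
    """Min-referenced binning: level(x) = floor((x - min_ROI)/width) + 1."""
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("cannot discretize an empty mask")
    vals = data[mask].astype(np.float64)
    mn = vals.min()
    labels = np.zeros(data.shape, dtype=np.int32)
    labels[mask] = np.floor((data[mask] - mn) / bin_width).astype(np.int32) + 1
    return DiscretizedROI(
        labels=labels,
        n_levels=int(labels.max()),
        bin_width=float(bin_width),
        roi_min=float(mn),
        spacing=tuple(spacing),
    )


def discretize(v, m: MaskVolume, bin_width: float = 25.0) -> DiscretizedROI:
    """Discretize a volume's ROI given its aligned mask."""
    m.check_aligned(v)
    return discretize_array(
        np.asarray(v.data, dtype=np.float64), m.data > 0, bin_width, v.spacing
    )
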