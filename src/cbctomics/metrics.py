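"""Segmentation overlap and surface-distance metrics (DSC, HD95, ASSD).

Surfaces are the face-connected boundary voxels of a mask (a mask voxel with
at least one background 6-neighbour, counting the outside of the grid as
background).  All distances are Euclidean in millimetres between voxel
centres, using the per-axis spacing.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volumes import MaskVolume

__all__ = [
    "dice_coefficient",
    "surface_voxels",
    "surface_distances",
    "hausdorff95",
    "assd",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def dice_coefficient(P: MaskVolume, G: MaskVolume) -> float:
    """2|P∩G| / (|P|+|G|); defined as 1.0 when both masks are empty."""
    P.check_aligned(G)
    p = P.data.astype(bool)
    g = G.data.astype(bool)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def surface_voxels(m: MaskVolume) -> np.ndarray:
    """(K, 3) integer indices of the face-connected boundary voxels."""
    data = m.data.astype(bool)
    eroded = ndimage.binary_erosion(data, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(data & ~eroded)


def surface_distances(A: MaskVolume, B: MaskVolume) -> tuple[np.ndarray, np.ndarray]:
    """Directed surface-distance sets (d(a, S(B)) for a in S(A), and vice versa)."""
    A.check_aligned(B)
    if A.voxel_count == 0 or B.voxel_count == 0:
        raise ValueError("surface distances require two nonempty masks")
    spacing = np.asarray(A.spacing)
    sa = surface_voxels(A) * spacing
    sb = surface_voxels(B) * spacing
    d_ab = cKDTree(sb).query(sa)[0]
    d_ba = cKDTree(sa).query(sb)[0]
    return d_ab, d_ba


def hausdorff95(A: MaskVolume, B: MaskVolume) -> float:
    """Symmetric 95th-percentile Hausdorff distance in mm.

    The two directed surface-distance sets are reduced to their 95th
    percentiles and combined with a max.
    """
    d_ab, d_ba = surface_distances(A, B)
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def assd(A: MaskVolume, B: MaskVolume) -> float:
    """Average symmetric surface distance in mm."""
    d_ab, d_ba = surface_distances(A, B)
    return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))
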