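"""Preprocessing chain: HU windowing, foreground crop, resampling and CLAHE.

The chain mirrors the standard soft-tissue preparation for rectal-tumor
segmentation: intensities are clamped to a (-200, 300) HU window, the volume
is cropped to its informative region, resampled to a fixed voxel grid with
linear interpolation (nearest-neighbour for masks), and contrast-enhanced
slice-by-slice with contrast-limited adaptive histogram equalization (CLAHE).
CLAHE operates per axial slice: each slice is tiled, per-tile histograms are
clipped and renormalised into CDF mappings, and the mappings are bilinearly
blended between tile centres.  The whole chain is deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import MaskVolume, Volume

__all__ = [
    "PreprocessConfig",
    "CropBox",
    "window_hu",
    "crop_to_foreground",
    "resample_to_shape",
    "clahe_enhance",
    "preprocess_case",
    "invert_mask_to_original",
]


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``clahe_clip_limit`` is the per-bin clip expressed as a fraction of the
    tile pixel count; ``target_shape`` of (256, 256, 128) is the full-scale
    profile, scaled runs use smaller grids.
    """

    hu_window: tuple[float, float] = (-200.0, 300.0)
    target_shape: tuple[int, int, int] = (256, 256, 128)
    crop_margin: int = 2
    #: "auto": mask bounding box when a mask is given, else intensity
    #: foreground; "intensity": always the intensity box (keeps training and
    #: inference crops consistent when the whole grid is informative)
    crop_mode: str = "auto"
    clahe_enabled: bool = True
    clahe_tile_grid: tuple[int, int] = (8, 8)
    clahe_n_bins: int = 256
    clahe_clip_limit: float = 0.01

    def __post_init__(self):
        lo, hi = self.hu_window
        if lo >= hi:
            raise ValueError(f"hu window lo must be < hi, got ({lo}, {hi})")
        if any(s <= 0 for s in self.target_shape):
            raise ValueError("target_shape must be positive")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe clip limit must be > 0")


@dataclass
class CropBox:
    """Records a crop so masks can be mapped back to the original grid."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]  # exclusive
    original_shape: tuple[int, int, int]

    @property
    def slices(self):
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))

    @property
    def shape(self):
        return tuple(h - l for l, h in zip(self.lo, self.hi))


def window_hu(v: Volume, lo: float, hi: float) -> Volume:
    """Clamp intensities to [lo, hi] voxelwise; geometry unchanged."""
    if lo >= hi:
        raise ValueError(f"window lo must be < hi, got ({lo}, {hi})")
    return v.with_data(np.clip(np.asarray(v.data, dtype=np.float64), lo, hi))


def crop_to_foreground(
    v: Volume,
    mask: MaskVolume | None = None,
    margin: int = 2,
    floor: float | None = None,
) -> tuple[Volume, MaskVolume | None, CropBox]:
    """Crop image (and mask) to the informative bounding box plus a margin.

    The box is the bounding box of the mask when one is given (training),
    otherwise of voxels strictly above ``floor`` (default: the volume
    minimum, i.e. the window floor after :func:`window_hu`).  The box is
    clipped to the grid and recorded for inversion.
    """
    data = np.asarray(v.data)
    if mask is not None:
        if mask.voxel_count == 0:
            raise ValueError("mask-guided crop requires a nonempty mask")
        mask.check_aligned(v)
        fg = mask.data > 0
    else:
        if floor is None:
            floor = float(data.min())
        fg = data > floor
        if not fg.any():
            raise ValueError("empty foreground: no voxel above the window floor")
    idx = np.nonzero(fg)
    lo = tuple(max(int(i.min()) - margin, 0) for i in idx)
    hi = tuple(min(int(i.max()) + 1 + margin, n) for i, n in zip(idx, data.shape))
    box = CropBox(lo=lo, hi=hi, original_shape=data.shape)
    v_out = v.with_data(data[box.slices])
    m_out = mask.with_data(mask.data[box.slices]) if mask is not None else None
    return v_out, m_out, box


def _resize_axis(data: np.ndarray, axis: int, n_new: int, order: int) -> np.ndarray:
    n_old = data.shape[axis]
    if n_new == n_old:
        return data
    t = (np.arange(n_new) + 0.5) * (n_old / n_new) - 0.5
    t = np.clip(t, 0, n_old - 1)
    moved = np.moveaxis(data, axis, -1)
    if order == 0:
        out = moved[..., np.rint(t).astype(int)]
    else:
        i0 = np.floor(t).astype(int)
        i1 = np.minimum(i0 + 1, n_old - 1)
        f = t - i0
        out = moved[..., i0] * (1 - f) + moved[..., i1] * f
    return np.moveaxis(out, -1, axis)


def resample_to_shape(v, shape: tuple[int, int, int], mode: str = "linear"):
    """Separable resize to an exact voxel grid, preserving physical extent.

    ``mode`` is ``"linear"`` for images or ``"nearest"`` for masks.  Spacing
    is rescaled by the old/new shape ratio so the field of view is unchanged.
    Accepts a :class:`Volume` or :class:`MaskVolume`.
    """
    if any(s <= 0 for s in shape):
        raise ValueError(f"target shape must be positive, got {shape}")
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    order = 1 if mode == "linear" else 0
    data = np.asarray(v.data, dtype=np.float64 if order else v.data.dtype)
    for ax in range(3):
        data = _resize_axis(data, ax, shape[ax], order)
    new_spacing = tuple(
        sp * n_old / n_new for sp, n_old, n_new in zip(v.spacing, v.shape, shape)
    )
    if isinstance(v, MaskVolume):
        return MaskVolume(data=data.astype(np.uint8), spacing=new_spacing, origin=v.origin)
    return Volume(data=data, spacing=new_spacing, origin=v.origin, modality=v.modality)


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def _tile_edges(n: int, tiles: int) -> np.ndarray:
    return np.linspace(0, n, tiles + 1).round().astype(int)


def _tile_mappings(u: np.ndarray, cfg: PreprocessConfig):
    """Per-tile clipped-histogram CDF mappings for one slice in [0, 1].

    Returns (mappings[gx, gy, n_bins], x_centers, y_centers).  Each mapping is
    a monotone non-decreasing CDF over the global [0, 1] bin grid.
    """
    gx, gy = cfg.clahe_tile_grid
    nx, ny = u.shape
    if gx > nx or gy > ny:
        raise ValueError(f"tile grid {cfg.clahe_tile_grid} larger than slice {u.shape}")
    nb = cfg.clahe_n_bins
    ex, ey = _tile_edges(nx, gx), _tile_edges(ny, gy)
    bins = np.minimum((u * nb).astype(int), nb - 1)
    maps = np.empty((gx, gy, nb))
    xc = np.empty(gx)
    yc = np.empty(gy)
    for i in range(gx):
        xc[i] = (ex[i] + ex[i + 1] - 1) / 2.0
        for j in range(gy):
            tile = bins[ex[i]:ex[i + 1], ey[j]:ey[j + 1]]
            npix = tile.size
            hist = np.bincount(tile.ravel(), minlength=nb).astype(np.float64)
            clip = max(cfg.clahe_clip_limit * npix, 1.0)
            excess = np.maximum(hist - clip, 0.0).sum()
            hist = np.minimum(hist, clip) + excess / nb
            cdf = np.cumsum(hist)
            maps[i, j] = cdf / cdf[-1]
    for j in range(gy):
        yc[j] = (ey[j] + ey[j + 1] - 1) / 2.0
    return maps, xc, yc


def _clahe_slice(u: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    maps, xc, yc = _tile_mappings(u, cfg)
    gx, gy = cfg.clahe_tile_grid
    nb = cfg.clahe_n_bins
    nx, ny = u.shape
    bins = np.minimum((u * nb).astype(int), nb - 1)

    # fractional tile coordinates of every pixel, clamped to the centre lattice
    tx = np.clip(np.interp(np.arange(nx), xc, np.arange(gx)), 0, gx - 1)
    ty = np.clip(np.interp(np.arange(ny), yc, np.arange(gy)), 0, gy - 1)
    ix0 = np.minimum(tx.astype(int), gx - 1 - (gx > 1))
    iy0 = np.minimum(ty.astype(int), gy - 1 - (gy > 1))
    fx = (tx - ix0)[:, None]
    fy = (ty - iy0)[None, :]
    ix1 = np.minimum(ix0 + 1, gx - 1)
    iy1 = np.minimum(iy0 + 1, gy - 1)

    IX0 = ix0[:, None]
    IX1 = ix1[:, None]
    IY0 = iy0[None, :]
    IY1 = iy1[None, :]
    m00 = maps[IX0, IY0, bins]
    m01 = maps[IX0, IY1, bins]
    m10 = maps[IX1, IY0, bins]
    m11 = maps[IX1, IY1, bins]
    return (
        m00 * (1 - fx) * (1 - fy)
        + m01 * (1 - fx) * fy
        + m10 * fx * (1 - fy)
        + m11 * fx * fy
    )


def clahe_enhance(v: Volume, cfg: PreprocessConfig) -> Volume:
    """Slice-wise CLAHE on a windowed volume; output stays in the HU window."""
    lo, hi = cfg.hu_window
    data = np.asarray(v.data, dtype=np.float64)
    if data.min() < lo - 1e-9 or data.max() > hi + 1e-9:
        raise ValueError("clahe_enhance expects an already-windowed volume")
    u = (data - lo) / (hi - lo)
    out = np.empty_like(u)
    for k in range(u.shape[2]):
        out[:, :, k] = _clahe_slice(u[:, :, k], cfg)
    return v.with_data(lo + out * (hi - lo))


def preprocess_case(
    v: Volume,
    mask: MaskVolume | None,
    cfg: PreprocessConfig,
    return_record: bool = False,
):
    """Full chain: window -> crop -> resample -> CLAHE (mask skips CLAHE).

    With ``return_record=True`` also returns a dict holding the crop box and
    shapes needed by :func:`invert_mask_to_original`.
    """
    vw = window_hu(v, *cfg.hu_window)
    crop_mask = mask if cfg.crop_mode == "auto" else None
    vc, _, box = crop_to_foreground(vw, crop_mask, margin=cfg.crop_margin)
    mc = mask.with_data(mask.data[box.slices]) if mask is not None else None
    vr = resample_to_shape(vc, cfg.target_shape, mode="linear")
    mr = resample_to_shape(mc, cfg.target_shape, mode="nearest") if mc is not None else None
    if cfg.clahe_enabled:
        vr = clahe_enhance(vr, cfg)
    if return_record:
        record = {"crop_box": box, "cropped_shape": vc.shape, "original": v}
        return vr, mr, record
    return vr, mr


def invert_mask_to_original(mask_proc: MaskVolume, record: dict) -> MaskVolume:
    """Map a mask on the processed grid back to the original volume geometry."""
    box: CropBox = record["crop_box"]
    orig: Volume = record["original"]
    m_crop = resample_to_shape(mask_proc, box.shape, mode="nearest")
    full = np.zeros(box.original_shape, dtype=np.uint8)
    full[box.slices] = m_crop.data
    return MaskVolume(data=full, spacing=orig.spacing, origin=orig.origin)
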