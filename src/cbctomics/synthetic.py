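"""Synthetic paired pCT/CBCT phantom cohorts with ground-truth tumor masks.

The generator emulates the statistical structure the downstream analysis
assumes: a soft-tissue background (smoothed Gaussian noise around a tissue
mean), a brighter lobulated tumor blob, and a CBCT counterpart of the same
anatomy degraded by extra noise, reduced contrast and a smooth multiplicative
shading (cupping) field, acquired at 3 mm slices and resampled back to the
5 mm pCT grid.  No projection/reconstruction physics is modelled.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import write_mask, write_volume
from .volumes import MaskVolume, Volume

__all__ = ["PhantomSpec", "generate_phantom", "degrade_to_cbct", "generate_cohort"]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic anatomy, tumor geometry and CBCT degradation.

    Defaults give a 48x48x48 voxel grid at pCT spacing (1, 1, 5) mm — 5 mm
    slices as acquired on a planning CT — with a soft-tissue background around
    30 HU and a tumor 20–60 HU brighter than tissue.  The CBCT counterpart is
    simulated at a native 3 mm slice spacing with roughly tripled noise, a 30 %
    contrast loss and a 15 % cupping-shading amplitude, then brought back to
    the 5 mm grid, mirroring how CBCT series are harmonised to the pCT
    geometry before paired analysis.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    pct_spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    cbct_spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    # background tissue
    tissue_mean: float = 30.0
    tissue_sigma: float = 10.0
    tissue_smooth_mm: float = 4.0
    # tumor geometry / contrast
    tumor_contrast: tuple[float, float] = (20.0, 60.0)
    tumor_radius_mm: tuple[float, float] = (8.0, 15.0)
    lobe_count: int = 4
    lobe_amp: float = 0.3
    # CBCT degradation
    cbct_noise_sigma: float = 15.0
    cbct_contrast_scale: float = 0.7
    cbct_shading_amp: float = 0.15
    seed: int = 0

    MARGIN_VOX: int = 2

    def __post_init__(self):
        if not (0.0 < self.cbct_contrast_scale <= 1.0):
            raise ValueError("cbct_contrast_scale must be in (0, 1]")
        if self.cbct_noise_sigma < 0:
            raise ValueError("cbct_noise_sigma must be >= 0")
        if self.tumor_radius_mm[0] > self.tumor_radius_mm[1]:
            raise ValueError("tumor_radius_mm range reversed")
        # tumor (largest radius, inflated by lobes) must fit with a 2-voxel margin
        r_max = self.tumor_radius_mm[1] * (1.0 + self.lobe_amp)
        for n, sp in zip(self.shape, self.pct_spacing):
            if r_max / sp + self.MARGIN_VOX > n / 2:
                raise ValueError(
                    f"tumor radius {self.tumor_radius_mm[1]} mm (+lobes) does not fit "
                    f"a {self.shape} grid at spacing {self.pct_spacing} with a "
                    f"{self.MARGIN_VOX}-voxel margin"
                )

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


def _coord_grids_mm(shape, spacing):
    axes = [np.arange(n) * sp for n, sp in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _smoothed_noise(rng, shape, spacing, sigma, smooth_mm):
    """Gaussian noise low-pass filtered to ``smooth_mm``, renormalised to ``sigma``."""
    raw = rng.standard_normal(shape)
    sig_vox = [smooth_mm / sp for sp in spacing]
    sm = ndimage.gaussian_filter(raw, sig_vox)
    sd = sm.std()
    if sd > 0:
        sm *= sigma / sd
    return sm


def generate_phantom(
    spec: PhantomSpec, return_geometry: bool = False
) -> tuple[Volume, MaskVolume]:
    """Generate one pCT-like phantom and its ground-truth tumor mask.

    The tumor is the union of a central ellipsoid and ``lobe_count`` perturbing
    spherical lobes seated on its surface; tumor voxels are brightened by a
    contrast sampled from ``tumor_contrast``.  Deterministic given the spec
    (including its seed).  With ``return_geometry=True`` a third element
    describes the sampled tumor (centre, semi-axes, contrast) for validation
    against analytic expectations.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.shape, spec.pct_spacing
    background = spec.tissue_mean + _smoothed_noise(
        rng, shape, spacing, spec.tissue_sigma, spec.tissue_smooth_mm
    )

    gx, gy, gz = _coord_grids_mm(shape, spacing)
    extent = [n * sp for n, sp in zip(shape, spacing)]
    r_base = rng.uniform(*spec.tumor_radius_mm)
    # per-axis semi-axes, clipped so the inflated tumor keeps the voxel margin
    semi = r_base * rng.uniform(0.75, 1.25, size=3)
    for i in range(3):
        lim = (shape[i] / 2 - spec.MARGIN_VOX) * spacing[i] / (1.0 + spec.lobe_amp)
        semi[i] = min(semi[i], lim)
    lo = [max(s * (1 + spec.lobe_amp), spec.MARGIN_VOX * sp) for s, sp in zip(semi, spacing)]
    center = np.array(
        [rng.uniform(l, e - l) if e > 2 * l else e / 2 for l, e in zip(lo, extent)]
    )

    inside = (
        ((gx - center[0]) / semi[0]) ** 2
        + ((gy - center[1]) / semi[1]) ** 2
        + ((gz - center[2]) / semi[2]) ** 2
    ) <= 1.0

    for _ in range(spec.lobe_count):
        if spec.lobe_amp <= 0:
            break
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        surf = center + d * semi  # point on the ellipsoid surface along d
        r_lobe = spec.lobe_amp * r_base * rng.uniform(0.5, 1.0)
        lobe = (
            (gx - surf[0]) ** 2 + (gy - surf[1]) ** 2 + (gz - surf[2]) ** 2
        ) <= r_lobe**2
        inside |= lobe

    contrast = rng.uniform(*spec.tumor_contrast)
    # partial-volume style soft edge: smooth the indicator by half a voxel
    soft = ndimage.gaussian_filter(inside.astype(np.float64), 0.5)
    data = background + contrast * soft

    vol = Volume(data=data, spacing=spacing, modality="PCT")
    mask = MaskVolume(data=inside.astype(np.uint8), spacing=spacing)
    if return_geometry:
        geometry = {"center_mm": center, "semi_axes_mm": semi, "contrast": contrast}
        return vol, mask, geometry
    return vol, mask


def _resample_z(data: np.ndarray, n_new: int, order: int) -> np.ndarray:
    """Separable resample along the slice axis to ``n_new`` slices."""
    n_old = data.shape[2]
    if n_new == n_old:
        return data.copy()
    # half-sample aligned coordinates (physical extent preserved)
    t = (np.arange(n_new) + 0.5) * (n_old / n_new) - 0.5
    t = np.clip(t, 0, n_old - 1)
    if order == 0:
        return data[:, :, np.rint(t).astype(int)]
    i0 = np.floor(t).astype(int)
    i1 = np.minimum(i0 + 1, n_old - 1)
    f = t - i0
    return data[:, :, i0] * (1 - f) + data[:, :, i1] * f


def degrade_to_cbct(
    v: Volume, mask: MaskVolume, spec: PhantomSpec
) -> tuple[Volume, MaskVolume]:
    """Derive the CBCT-like counterpart of a pCT phantom.

    Resamples to the native CBCT slice spacing, scales contrast about the
    tissue mean, applies a separable cosine shading (cupping) field, adds
    noise, and resamples back to the pCT slice spacing.  The mask travels by
    nearest-neighbour through the same round-trip.
    """
    mask.check_aligned(v)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7]))
    z_pct, z_cbct = v.spacing[2], spec.cbct_spacing[2]
    n_pct = v.shape[2]
    n_native = max(2, int(round(n_pct * z_pct / z_cbct)))

    img = _resample_z(np.asarray(v.data, dtype=np.float64), n_native, order=1)
    msk = _resample_z(mask.data, n_native, order=0)

    img = spec.tissue_mean + spec.cbct_contrast_scale * (img - spec.tissue_mean)

    if spec.cbct_shading_amp != 0:
        nx, ny = img.shape[:2]
        cx = np.cos(np.pi * (np.arange(nx) / max(nx - 1, 1) - 0.5))
        cy = np.cos(np.pi * (np.arange(ny) / max(ny - 1, 1) - 0.5))
        shade = 1.0 + spec.cbct_shading_amp * np.outer(cx, cy)
        img = img * shade[:, :, None]

    if spec.cbct_noise_sigma > 0:
        img = img + rng.normal(0.0, spec.cbct_noise_sigma, size=img.shape)

    img = _resample_z(img, n_pct, order=1)
    msk = _resample_z(msk, n_pct, order=0)

    out = Volume(data=img, spacing=v.spacing, origin=v.origin, modality="CBCT")
    out_mask = MaskVolume(data=msk, spacing=v.spacing, origin=v.origin)
    return out, out_mask


def generate_cohort(n: int, spec: PhantomSpec, out_dir) -> pd.DataFrame:
    """Write ``n`` paired cases (4 NIfTI files each) plus a manifest CSV.

    Per-case seeds are ``spec.seed + index`` so cohorts are reproducible and
    cases independent.  Returns the manifest (also saved as
    ``manifest.csv`` in ``out_dir``).
    """
    if n < 2:
        raise ValueError("cohort needs at least 2 cases")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n):
        case = f"case_{i:03d}"
        cspec = spec.replace(seed=spec.seed + i)
        pct, pmask = generate_phantom(cspec)
        cbct, cmask = degrade_to_cbct(pct, pmask, cspec)
        paths = {
            "pct_path": out_dir / f"{case}_pct.nii.gz",
            "pct_mask_path": out_dir / f"{case}_pct_mask.nii.gz",
            "cbct_path": out_dir / f"{case}_cbct.nii.gz",
            "cbct_mask_path": out_dir / f"{case}_cbct_mask.nii.gz",
        }
        write_volume(pct, paths["pct_path"])
        write_mask(pmask, paths["pct_mask_path"])
        write_volume(cbct, paths["cbct_path"])
        write_mask(cmask, paths["cbct_mask_path"])
        rows.append({"case_id": case, **{k: str(p) for k, p in paths.items()}})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def generate_cohort_arrays(
    n: int, spec: PhantomSpec
) -> list[dict]:
    """In-memory variant of :func:`generate_cohort` (no files written).

    Returns one dict per case with keys ``case_id, pct, pct_mask, cbct,
    cbct_mask``.
    """
    if n < 2:
        raise ValueError("cohort needs at least 2 cases")
    cases = []
    for i in range(n):
        cspec = spec.replace(seed=spec.seed + i)
        pct, pmask = generate_phantom(cspec)
        cbct, cmask = degrade_to_cbct(pct, pmask, cspec)
        cases.append(
            {
                "case_id": f"case_{i:03d}",
                "pct": pct,
                "pct_mask": pmask,
                "cbct": cbct,
                "cbct_mask": cmask,
            }
        )
    return cases
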