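"""Feature extraction driver: derived images -> classes -> named features."""
from __future__ import annotations

import numpy as np

from ..volumes import MaskVolume, Volume
from .discretize import DiscretizedROI, discretize_array
from .filters import (
    gradient_magnitude,
    intensity_transforms,
    log_filter,
    wavelet_subbands,
)
from .firstorder import firstorder_features
from .manifest import FeatureManifest, default_manifest
from .matrices import (
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from .shape import shape_features

__all__ = ["compute_class_features", "extract_features"]

_MATRIX_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "gldm": gldm_features,
    "ngtdm": ngtdm_features,
}


def compute_class_features(
    data: np.ndarray,
    mask: np.ndarray,
    spacing,
    cls: str,
    bin_width: float = 25.0,
    _d_cache: dict | None = None,
) -> dict[str, float]:
    """All features of one class on one (derived) image."""
    if cls == "firstorder":
        return firstorder_features(data, mask, spacing, bin_width)
    if cls not in _MATRIX_FUNCS:
        raise ValueError(f"unknown feature class {cls!r}")
    if _d_cache is not None and "d" in _d_cache:
        d = _d_cache["d"]
    else:
        d = discretize_array(data, mask, bin_width, spacing)
        if _d_cache is not None:
            _d_cache["d"] = d
    return _MATRIX_FUNCS[cls](d)


def _derived_image(image_type: str, v: Volume, manifest: FeatureManifest, cache: dict):
    if image_type in cache:
        return cache[image_type]
    data = np.asarray(v.data, dtype=np.float64)
    if image_type == "original":
        img = data
    elif image_type == "gradient":
        img = gradient_magnitude(data, v.spacing)
    elif image_type.startswith("wavelet-"):
        bands = wavelet_subbands(data, manifest.wavelet)
        for name, band in bands.items():
            cache[f"wavelet-{name}"] = band
        img = cache[image_type]
    elif image_type.startswith("log-sigma-"):
        sigma = float(image_type[len("log-sigma-"):-2])
        img = log_filter(data, v.spacing, sigma)
    else:  # intensity transform
        for name, t in intensity_transforms(data).items():
            cache[name] = t
        img = cache[image_type]
    cache[image_type] = img
    return img


def extract_features(
    v: Volume, m: MaskVolume, manifest: FeatureManifest | None = None
) -> dict[str, float]:
    """Extract every manifest feature from an aligned volume/mask pair.

    Returns an ordered ``{name: value}`` mapping whose names carry the
    image-type and class provenance
    (``<imageType>_<class>_<Name>``).  Deterministic: repeated calls give
    bitwise-identical vectors.
    """
    if manifest is None:
        manifest = default_manifest()
    m.check_aligned(v)
    if m.voxel_count == 0:
        raise ValueError("feature extraction requires a nonempty mask")
    mask = m.data > 0

    out: dict[str, float] = {}
    image_cache: dict[str, np.ndarray] = {}
    for image_type in manifest.image_types():
        classes = manifest.classes_for(image_type)
        if image_type == "original" and "shape" in classes:
            sf = shape_features(m)
            for f in manifest.features_for("original", "shape"):
                out[manifest.full_name("original", "shape", f)] = sf[f]
            classes = [c for c in classes if c != "shape"]
        if not classes:
            continue
        img = _derived_image(image_type, v, manifest, image_cache)
        d_cache: dict = {}
        for cls in classes:
            vals = compute_class_features(
                img, mask, v.spacing, cls, manifest.bin_width, d_cache
            )
            for f in manifest.features_for(image_type, cls):
                out[manifest.full_name(image_type, cls, f)] = vals[f]
    return out
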