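"""The feature manifest: which (image type, class, feature) triples to emit.

The packaged default manifest reproduces a 1037-feature inventory per image,
decomposed as 14 shape / 19 first-order / 172 texture / 728 wavelet /
104 LoG.  Its composition (declared here, not hard-coded in the extractor):

* ``original``: 14 shape + 19 first-order + all 75 matrix features
  (GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5);
* intensity transforms ``square/squareroot/logarithm/exponential``:
  19 first-order each;
* ``gradient`` (gradient magnitude): GLRLM + NGTDM (21);
* 8 wavelet sub-bands: a 16-feature first-order subset plus all 75 matrix
  features each (on filtered images the raw extrema Minimum/Maximum/Range
  are dominated by isolated filter-response peaks and are omitted);
* LoG: GLCM at sigma 1, 2, 3 mm and GLRLM at sigma 1, 2 mm.

Feature categories are recovered from the image-type prefix: ``wavelet-*``
-> wavelet, ``log-sigma-*`` -> LoG, original shape/first-order stand alone,
and everything else (matrix features on the original plus all transform
images) is texture.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .filters import TRANSFORM_NAMES

__all__ = [
    "SHAPE_NAMES",
    "FIRSTORDER_NAMES",
    "FIRSTORDER_FILTERED_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
    "MATRIX_CLASSES",
    "FeatureManifest",
    "default_manifest",
    "firstorder_only_manifest",
]

SHAPE_NAMES = (
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Compactness1",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)

FIRSTORDER_NAMES = (
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
    "StandardDeviation",
)

#: First-order subset used on filtered (wavelet) images.
FIRSTORDER_FILTERED_NAMES = tuple(
    n for n in FIRSTORDER_NAMES if n not in ("Minimum", "Maximum", "Range")
)

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
)

GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

MATRIX_CLASSES = {
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "gldm": GLDM_NAMES,
    "ngtdm": NGTDM_NAMES,
}

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

CATEGORIES = ("shape", "firstorder", "texture", "wavelet", "log")


@dataclass
class FeatureManifest:
    """Ordered list of (image_type, class, feature) triples plus parameters."""

    entries: list[tuple[str, str, str]]
    bin_width: float = 25.0
    wavelet: str = "coif1"

    def __post_init__(self):
        names = [self.full_name(*e) for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("manifest contains duplicate feature names")
        if self.bin_width <= 0:
            raise ValueError("bin width must be > 0")

    @staticmethod
    def full_name(image_type: str, cls: str, feature: str) -> str:
        return f"{image_type}_{cls}_{feature}"

    @property
    def feature_names(self) -> list[str]:
        return [self.full_name(*e) for e in self.entries]

    @staticmethod
    def category_of(image_type: str, cls: str) -> str:
        if image_type == "original":
            if cls == "shape":
                return "shape"
            if cls == "firstorder":
                return "firstorder"
            return "texture"
        if image_type.startswith("wavelet-"):
            return "wavelet"
        if image_type.startswith("log-sigma"):
            return "log"
        return "texture"

    def category_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(CATEGORIES, 0)
        for it, cls, _ in self.entries:
            counts[self.category_of(it, cls)] += 1
        return counts

    def image_types(self) -> list[str]:
        seen = {}
        for it, _, _ in self.entries:
            seen.setdefault(it, None)
        return list(seen)

    def classes_for(self, image_type: str) -> list[str]:
        seen = {}
        for it, cls, _ in self.entries:
            if it == image_type:
                seen.setdefault(cls, None)
        return list(seen)

    def features_for(self, image_type: str, cls: str) -> list[str]:
        return [f for it, c, f in self.entries if it == image_type and c == cls]


def _log_image_type(sigma_mm: float) -> str:
    return f"log-sigma-{sigma_mm:g}mm"


def default_manifest(bin_width: float = 25.0, wavelet: str = "coif1") -> FeatureManifest:
    """The packaged 1037-feature manifest (see module docstring)."""
    entries: list[tuple[str, str, str]] = []
    add = entries.append
    for f in SHAPE_NAMES:
        add(("original", "shape", f))
    for f in FIRSTORDER_NAMES:
        add(("original", "firstorder", f))
    for cls, names in MATRIX_CLASSES.items():
        for f in names:
            add(("original", cls, f))
    for t in TRANSFORM_NAMES:
        for f in FIRSTORDER_NAMES:
            add((t, "firstorder", f))
    for f in GLRLM_NAMES:
        add(("gradient", "glrlm", f))
    for f in NGTDM_NAMES:
        add(("gradient", "ngtdm", f))
    for band in WAVELET_SUBBANDS:
        it = f"wavelet-{band}"
        for f in FIRSTORDER_FILTERED_NAMES:
            add((it, "firstorder", f))
        for cls, names in MATRIX_CLASSES.items():
            for f in names:
                add((it, cls, f))
    for sigma in (1.0, 2.0, 3.0):
        for f in GLCM_NAMES:
            add((_log_image_type(sigma), "glcm", f))
    for sigma in (1.0, 2.0):
        for f in GLRLM_NAMES:
            add((_log_image_type(sigma), "glrlm", f))
    return FeatureManifest(entries=entries, bin_width=bin_width, wavelet=wavelet)


def firstorder_only_manifest(bin_width: float = 25.0) -> FeatureManifest:
    """Reduced manifest (original first-order only) for quick cohort studies."""
    entries = [("original", "firstorder", f) for f in FIRSTORDER_NAMES]
    return FeatureManifest(entries=entries, bin_width=bin_width)
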