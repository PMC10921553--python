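"""Core in-memory containers for 3D scalar images and binary masks.

Arrays are indexed ``(x, y, z)`` with ``z`` the slice axis; ``spacing`` and
``origin`` are millimetres in the same axis order.  All physical distances in
the package are computed with the per-axis spacing of these containers.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Recognised modality tags.
MODALITIES = ("PCT", "CBCT")


def _as_tuple3(v, name: str) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"{name} must have 3 components, got {len(t)}")
    return t


@dataclass
class Volume:
    """A 3D scalar image (HU or enhanced intensity) with geometry and modality.

    Parameters
    ----------
    data
        3D array of scalar intensities.
    spacing
        Voxel size in mm along (x, y, z); all components must be positive.
    origin
        Position of voxel (0, 0, 0) in mm.
    modality
        Either ``"PCT"`` or ``"CBCT"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "PCT"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got {self.data.ndim} axes")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, **kw) -> "Volume":
        """Copy of this volume with new voxel data (same geometry)."""
        return replace(self, data=data, **kw)

    def same_geometry(self, other, atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class MaskVolume:
    """Binary tumor mask aligned to a :class:`Volume` (values in {0, 1})."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"mask data must be 3D, got {self.data.ndim} axes")
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0, 1}}, found {vals[:10]}")
        self.data = self.data.astype(np.uint8)
        self.spacing = _as_tuple3(self.spacing, "spacing")
        self.origin = _as_tuple3(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def with_data(self, data: np.ndarray) -> "MaskVolume":
        return replace(self, data=data)

    def same_geometry(self, other, atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def check_aligned(self, other) -> None:
        if not self.same_geometry(other):
            raise ValueError(
                "geometry mismatch: "
                f"{self.shape}/{self.spacing} vs {other.shape}/{other.spacing}"
            )
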