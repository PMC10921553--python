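"""Reading and writing of volumes, masks and feature tables.

The canonical on-disk image format is NIfTI (written with a diagonal affine
built from spacing/origin).  DICOM series are supported read-only: slices of a
single series are sorted by their position along the slice axis.  Feature
tables are CSV with the case id in the first column and one column per
feature.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .volumes import MODALITIES, MaskVolume, Volume

__all__ = [
    "FeatureTable",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_feature_table",
    "write_feature_table",
]


# ---------------------------------------------------------------------------
# NIfTI / DICOM volumes
# ---------------------------------------------------------------------------

def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(v: Volume, path) -> None:
    """Write a volume as NIfTI; geometry round-trips to <= 1e-6 mm."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(v.data), _affine(v.spacing, v.origin))
    img.header.set_xyzt_units("mm")
    # Stash the modality tag in the free-text description field.
    img.header["descrip"] = f"modality={v.modality}".encode()
    nib.save(img, str(path))


def _read_nifti(path: Path) -> Volume:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.ndim} axes")
    aff = img.affine
    spacing = tuple(float(x) for x in np.linalg.norm(aff[:3, :3], axis=0))
    origin = tuple(float(x) for x in aff[:3, 3])
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(errors="ignore")
    modality = "PCT"
    if descrip.startswith("modality="):
        tag = descrip.split("=", 1)[1]
        if tag in MODALITIES:
            modality = tag
    data = np.asanyarray(img.dataobj)
    return Volume(data=data, spacing=spacing, origin=origin, modality=modality)


def _read_dicom_series(path: Path) -> Volume:
    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"{path}: empty directory, no DICOM slices found")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception as e:  # not a DICOM file
            raise ValueError(f"{f}: not a readable DICOM slice ({e})") from e
        slices.append(ds)
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) != 1:
        raise ValueError(f"{path}: directory holds {len(uids)} different series")
    # Sort by position along the slice axis (z component of ImagePositionPatient).
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = [float(ds.ImagePositionPatient[2]) for ds in slices]
    rows = {(int(ds.Rows), int(ds.Columns)) for ds in slices}
    if len(rows) != 1:
        raise ValueError(f"{path}: inconsistent slice shapes {rows}")
    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        inter = float(getattr(ds, "RescaleIntercept", 0.0))
        # pixel_array is (row, col) = (y, x); transpose to (x, y)
        planes.append((arr * slope + inter).T)
    data = np.stack(planes, axis=-1)
    ds0 = slices[0]
    px = [float(x) for x in ds0.PixelSpacing]  # (row spacing, col spacing)
    dz = float(np.mean(np.diff(zs))) if len(zs) > 1 else float(
        getattr(ds0, "SliceThickness", 1.0)
    )
    origin = tuple(float(x) for x in ds0.ImagePositionPatient)
    return Volume(data=data, spacing=(px[1], px[0], abs(dz)), origin=origin)


def read_volume(path) -> Volume:
    """Read a NIfTI file or a directory holding one DICOM series."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        return _read_dicom_series(path)
    return _read_nifti(path)


def write_mask(m: MaskVolume, path) -> None:
    vals = np.unique(m.data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask contains values outside {{0, 1}}: {vals[:10]}")
    write_volume(
        Volume(data=m.data.astype(np.uint8), spacing=m.spacing, origin=m.origin),
        path,
    )


def read_mask(path) -> MaskVolume:
    v = read_volume(path)
    vals = np.unique(v.data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path}: mask file contains values outside {{0, 1}}")
    return MaskVolume(data=v.data.astype(np.uint8), spacing=v.spacing, origin=v.origin)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Case x feature matrix of radiomic values.

    Feature names follow the ``<imageType>_<class>_<Name>`` convention
    (e.g. ``wavelet-HLH_glrlm_GrayLevelNonUniformity``).
    """

    case_ids: list[str]
    feature_names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.case_ids = [str(c) for c in self.case_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(set(self.feature_names)) != len(self.feature_names):
            dupes = pd.Series(self.feature_names)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate feature names: {dupes[:5]}")
        if self.values.shape != (len(self.case_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.case_ids)} cases x {len(self.feature_names)} features"
            )

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "case_id", self.case_ids)
        return df

    @classmethod
    def from_rows(cls, rows: dict[str, dict[str, float]]) -> "FeatureTable":
        """Build from ``{case_id: {feature: value}}`` (all rows same keys)."""
        case_ids = list(rows)
        names = list(next(iter(rows.values())))
        vals = np.array([[rows[c][f] for f in names] for c in case_ids])
        return cls(case_ids=case_ids, feature_names=names, values=vals)


def write_feature_table(t: FeatureTable, path) -> None:
    """Write a CSV (first column case id); values keep 12 significant digits."""
    t.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path) -> FeatureTable:
    path = Path(path)
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln]
    header = lines[0].split(",")
    if header[0] != "case_id":
        raise ValueError(f"{path}: first column must be 'case_id', got {header[0]!r}")
    names = header[1:]
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate feature names in header")
    for i, ln in enumerate(lines[1:], start=2):
        if ln.count(",") != len(names):
            raise ValueError(f"{path}: ragged row at line {i}")
    df = pd.read_csv(path, dtype={"case_id": str})
    return FeatureTable(
        case_ids=list(df["case_id"]),
        feature_names=names,
        values=df[names].to_numpy(dtype=np.float64),
    )
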