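"""Volume, mask and table I/O with the package's geometry and label conventions.

Conventions
-----------
* In-memory arrays are indexed ``(slice, row, col)``, 0-based.  The slice
  axis is the scanner's z axis; spacing along it is slice thickness plus
  inter-slice gap.
* All physical lengths are millimetres; intensities are arbitrary scanner
  units and must be finite and non-negative.
* Label images carry exactly one integer label per voxel, with a label
  dictionary mapping reserved anatomical names to integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: Canonical label dictionary used by the phantom and the pipeline.
#: ``muscle_margin`` / ``fat_margin`` are anatomical muscle / subcutaneous
#: fat within the safety margin of a tissue interface; they are imaged as
#: their tissue but excluded from the analysed regions (conservative
#: delineation).
CANONICAL_LABELS: dict[str, int] = {
    "background": 0,
    "subcut_fat": 1,
    "muscle_ant_R": 2,
    "muscle_post_R": 3,
    "muscle_ant_L": 4,
    "muscle_post_L": 5,
    "cortical_bone_R": 6,
    "cortical_bone_L": 7,
    "marrow_R": 8,
    "marrow_L": 9,
    "muscle_margin": 10,
    "fat_margin": 11,
}

#: The four analysed muscle compartments (right/left x anterior/posterior).
MUSCLE_ROIS: tuple[str, ...] = (
    "muscle_ant_R",
    "muscle_post_R",
    "muscle_ant_L",
    "muscle_post_L",
)

MARROW_LABELS: tuple[str, ...] = ("marrow_R", "marrow_L")

#: Column schema for clinical tables (one row per subject-visit).
CLINICAL_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "visit_index",
    "visit_time_years",
    "mrc_right_thigh",
    "mrc_left_thigh",
    "mrcs",
    "css",
    "mfm_d1_pct",
    "mfm_d2_pct",
    "mfm_d3_pct",
    "mfm_total_pct",
    "bmi",
    "d4z4_ru",
)


@dataclass
class VolumeImage:
    """A 3D intensity grid with voxel geometry.

    Parameters
    ----------
    data
        3D array of finite, non-negative intensities, axis order
        ``(slice, row, col)``.
    spacing_mm
        Physical spacing per axis in the same order.  The slice spacing
        includes the inter-slice gap.
    orientation
        Axis-order convention tag; only ``"SRC"`` (slice, row, col) is used.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    orientation: str = "SRC"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data: expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data: intensities must all be finite")
        if np.any(self.data < 0):
            raise ValueError("data: intensities must be non-negative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm: must be 3 strictly positive values, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMask:
    """Integer label grid aligned to a :class:`VolumeImage`."""

    labels: np.ndarray
    label_names: dict[str, int] = field(default_factory=lambda: dict(CANONICAL_LABELS))
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(
                f"labels: expected a 3D grid, got {self.labels.ndim} dimensions"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise ValueError("labels: must be integer-valued")
            self.labels = self.labels.astype(np.int16)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def values_for(self, label_names) -> list[int]:
        """Integer codes for the given names; raises listing alternatives."""
        codes = []
        for name in label_names:
            if name not in self.label_names:
                raise KeyError(
                    f"unknown label {name!r}; available labels: "
                    f"{sorted(self.label_names)}"
                )
            codes.append(self.label_names[name])
        return codes

    def region(self, label_names) -> np.ndarray:
        """Boolean voxel mask for the union of the named labels."""
        codes = self.values_for(label_names)
        return np.isin(self.labels, codes)


def check_aligned(volume: VolumeImage, mask: LabelMask) -> None:
    """Raise if a mask cannot be paired with a volume."""
    if volume.shape != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )


def roi_voxels(volume: VolumeImage, mask: LabelMask, label_names) -> np.ndarray:
    """Intensities of exactly the voxels carrying any of the named labels.

    Returns a 1D array (the intensity multiset); ``len`` of the result is
    the voxel count.  An unknown label name raises, listing the labels that
    do exist.
    """
    check_aligned(volume, mask)
    return volume.data[mask.region(label_names)]


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def write_volume(volume: VolumeImage, path) -> None:
    img = nib.Nifti1Image(volume.data, _affine(volume.spacing_mm))
    img.header.set_data_dtype(np.float64)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_volume(path) -> VolumeImage:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim} dimensions")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(np.asarray(data, dtype=np.float64), spacing)


def _sidecar_path(path) -> Path:
    s = str(path)
    for suffix in (".nii.gz", ".nii"):
        if s.endswith(suffix):
            return Path(s[: -len(suffix)] + ".labels.json")
    return Path(s + ".labels.json")


def write_mask(mask: LabelMask, path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(mask.spacing_mm))
    img.header.set_data_dtype(np.int16)
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps(mask.label_names, indent=1))


def read_mask(path, volume: VolumeImage | None = None) -> LabelMask:
    img = nib.load(str(path))
    labels = np.asanyarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label grid, got {labels.ndim} dimensions")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = _sidecar_path(path)
    names = json.loads(sidecar.read_text()) if sidecar.exists() else dict(CANONICAL_LABELS)
    mask = LabelMask(labels.astype(np.int16), names, spacing)
    if volume is not None:
        check_aligned(volume, mask)
    return mask


# ---------------------------------------------------------------------------
# Clinical tables


def write_clinical(records: pd.DataFrame, path) -> None:
    missing = [c for c in CLINICAL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"clinical table is missing columns: {missing}")
    records.to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table is missing columns: {missing}")
    return df
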