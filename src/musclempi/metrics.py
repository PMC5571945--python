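"""Mean pixel intensity (MPI) per compartment, per thigh, and overall.

MPI over an ROI is the sum of normalized voxel intensities divided by the
voxel count — the arithmetic mean, pooled over all slices of the ROI.  It
rises both when fat infiltrates muscle (bright voxels replace dark ones)
and when muscle volume shrinks relative to residual bright tissue, which
is what makes it a disease-progression index.  Pooled values (per thigh,
per compartment across sides, both thighs) pool the voxels themselves,
i.e. they are voxel-count-weighted means of the constituent ROI MPIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .normalize import NormalizedVolume
from .volio import LabelMask

#: MPIResult ROI keys -> mask label names
ROI_LABELS = {
    "right_ant": "muscle_ant_R",
    "right_post": "muscle_post_R",
    "left_ant": "muscle_ant_L",
    "left_post": "muscle_post_L",
}

POOLED_GROUPS = {
    "mpi_right": ("right_ant", "right_post"),
    "mpi_left": ("left_ant", "left_post"),
    "mpi_anterior": ("right_ant", "left_ant"),
    "mpi_posterior": ("right_post", "left_post"),
    "mpi_total": ("right_ant", "right_post", "left_ant", "left_post"),
}


@dataclass
class MPIResult:
    """MPI values for one subject-visit."""

    subject_id: str
    visit_index: int
    mpi_by_roi: dict[str, float]
    mpi_right: float
    mpi_left: float
    mpi_anterior: float
    mpi_posterior: float
    mpi_total: float
    voxel_counts: dict[str, int]

    def as_row(self) -> dict:
        row = {"subject_id": self.subject_id, "visit_index": self.visit_index}
        for k in ROI_LABELS:
            row[f"mpi_{k}"] = self.mpi_by_roi[k]
            row[f"n_{k}"] = self.voxel_counts[k]
        for k in POOLED_GROUPS:
            row[k] = getattr(self, k)
        return row


def results_table(results) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


def compute_mpi(norm: NormalizedVolume, mask: LabelMask, labels) -> float:
    """Arithmetic mean of normalized intensity over the named labels."""
    vox = norm.data[mask.region(labels)]
    if vox.size == 0:
        raise ValueError(f"ROI {tuple(labels)} is empty")
    return float(vox.mean())


def compute_all(
    norm: NormalizedVolume,
    mask: LabelMask,
    subject_id: str = "",
    visit_index: int = 0,
) -> MPIResult:
    """MPI for each compartment plus every pooled combination."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for key, label in ROI_LABELS.items():
        vox = norm.data[mask.region([label])]
        if vox.size == 0:
            raise ValueError(f"ROI {label!r} is empty")
        sums[key] = float(vox.sum())
        counts[key] = int(vox.size)
    mpi_by_roi = {k: sums[k] / counts[k] for k in ROI_LABELS}
    pooled = {
        name: sum(sums[k] for k in keys) / sum(counts[k] for k in keys)
        for name, keys in POOLED_GROUPS.items()
    }
    return MPIResult(
        subject_id=subject_id,
        visit_index=visit_index,
        mpi_by_roi=mpi_by_roi,
        voxel_counts=counts,
        **pooled,
    )
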