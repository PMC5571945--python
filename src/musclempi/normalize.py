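"""Marrow-referenced intensity normalization and ROI histograms.

The fatty marrow in the femoral lumen is the brightest stable reference
tissue on T1-weighted images; mapping its intensity to 100% puts muscle
and fat on a subject-independent scale.  Normalization is the two-point
linear map 0 -> 0, reference -> 100; values above 100 are permitted (fat
or marrow voxels brighter than the reference are not clipped), and the
map is strictly monotone, so voxel rankings are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import MARROW_LABELS, LabelMask, VolumeImage, check_aligned


@dataclass
class NormalizedVolume:
    """Volume in normalized % units, with the raw reference used."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    reference_value: float


@dataclass
class NormalizedHistogram:
    """Volume-fraction distribution over normalized intensity for an ROI."""

    bin_edges: np.ndarray  # uniform width, normalized % units
    volume_fraction_pct: np.ndarray  # per-bin % of ROI voxels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "volume_fraction_pct": self.volume_fraction_pct,
            }
        )


def marrow_reference(
    volume: VolumeImage,
    mask: LabelMask,
    labels=MARROW_LABELS,
    statistic: str = "median",
) -> float:
    """Reference intensity over the femoral marrow lumen, both sides pooled.

    The median (default) is robust to cortical-bone partial volume at the
    lumen boundary; the mean is available for sensitivity analyses.
    """
    check_aligned(volume, mask)
    present = [n for n in labels if n in mask.label_names]
    if not present:
        raise ValueError(f"no marrow labels among {labels} in mask")
    vox = volume.data[mask.region(present)]
    if vox.size == 0:
        raise ValueError("marrow mask is empty")
    if statistic == "median":
        return float(np.median(vox))
    if statistic == "mean":
        return float(vox.mean())
    raise ValueError(f"unknown reference statistic {statistic!r}")


def marrow_from_bone_mask(
    mask: LabelMask, bone_labels=("cortical_bone_R", "cortical_bone_L")
) -> np.ndarray:
    """Derive a marrow region by eroding a whole-bone mask by one voxel.

    For masks where only the whole femur was delineated, the lumen is
    approximated as the erosion interior of the bone mask (in-plane).
    """
    bone = mask.region(bone_labels)
    structure = np.zeros((1, 3, 3), dtype=bool)
    structure[0] = True
    return ndimage.binary_erosion(bone, structure=structure)


def normalize_volume(volume: VolumeImage, reference: float) -> NormalizedVolume:
    """Linear two-point normalization: 0 -> 0, ``reference`` -> 100."""
    if reference <= 0:
        raise ValueError(f"reference must be positive, got {reference}")
    return NormalizedVolume(
        100.0 * (volume.data / reference), volume.spacing_mm, float(reference)
    )


def roi_histogram(
    norm: NormalizedVolume,
    mask: LabelMask,
    labels,
    bin_width_pct: float = 1.0,
) -> NormalizedHistogram:
    """Histogram of normalized intensity over an ROI, in % of ROI voxels.

    Bins are uniform over [0, max(120, ROI max)], so the bright fat mode
    near and above 100 is always covered.
    """
    if bin_width_pct <= 0:
        raise ValueError("bin width must be positive")
    vox = norm.data[mask.region(labels)]
    if vox.size == 0:
        raise ValueError(f"ROI {labels} is empty")
    top = max(120.0, float(vox.max()))
    n_bins = int(np.ceil(top / bin_width_pct))
    edges = np.arange(n_bins + 1) * bin_width_pct
    counts, edges = np.histogram(vox, bins=edges)
    return NormalizedHistogram(edges, 100.0 * counts / vox.size)
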