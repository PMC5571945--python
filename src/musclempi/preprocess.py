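"""Bias-field correction, within-subject template building and mask propagation.

The within-subject motion model is rigid: thigh repositioning between
sessions at this scale is dominated by translation and small rotation, and
a rigid model is exactly invertible, which keeps template-space masks and
visit-space masks consistent.  Registration uses a mean-squares metric with
full voxel sampling, so results are deterministic.

Bias correction replaces the usual N4 step with an explicit contract: a
smooth low-order in-plane polynomial fitted to log intensities over a
caller-chosen tissue region, normalized to mean 1 over that region, and
divided out.  This matches the single-coil shading the phantom applies and
makes the corrected image scale with the input (no intensity re-windowing).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .volio import LabelMask, VolumeImage, check_aligned


# ---------------------------------------------------------------------------
# Rigid transforms


@dataclass
class RigidTransform:
    """Rigid (Euler) transform of physical points.

    ``rotation_deg`` are rotations about the physical x (column), y (row)
    and z (slice) axes; ``translation_mm`` likewise in (x, y, z) order;
    ``center_mm`` is the rotation centre.  The convention is that the
    transform maps points in visit space to points in template space.
    """

    rotation_deg: tuple[float, float, float]
    translation_mm: tuple[float, float, float]
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    convention: str = "visit_to_template"

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls((0.0, 0.0, 0.0), (0.0, 0.0, 0.0))

    def is_identity(self, tol: float = 0.0) -> bool:
        return all(abs(v) <= tol for v in self.rotation_deg) and all(
            abs(v) <= tol for v in self.translation_mm
        )

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        t.SetCenter([float(c) for c in self.center_mm])
        t.SetRotation(*[math.radians(a) for a in self.rotation_deg])
        t.SetTranslation([float(v) for v in self.translation_mm])
        return t

    @classmethod
    def from_sitk(
        cls, t: sitk.Euler3DTransform, convention: str = "visit_to_template"
    ) -> "RigidTransform":
        return cls(
            rotation_deg=(
                math.degrees(t.GetAngleX()),
                math.degrees(t.GetAngleY()),
                math.degrees(t.GetAngleZ()),
            ),
            translation_mm=tuple(float(v) for v in t.GetTranslation()),
            center_mm=tuple(float(v) for v in t.GetCenter()),
            convention=convention,
        )

    def inverse(self) -> "RigidTransform":
        inv = sitk.Euler3DTransform(self.to_sitk().GetInverse())
        conv = (
            "template_to_visit"
            if self.convention == "visit_to_template"
            else "visit_to_template"
        )
        return RigidTransform.from_sitk(inv, convention=conv)

    def to_dict(self) -> dict:
        return {
            "rotation_deg": list(self.rotation_deg),
            "translation_mm": list(self.translation_mm),
            "center_mm": list(self.center_mm),
            "convention": self.convention,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            tuple(d["rotation_deg"]),
            tuple(d["translation_mm"]),
            tuple(d.get("center_mm", (0.0, 0.0, 0.0))),
            d.get("convention", "visit_to_template"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# SimpleITK bridging (array axis order (slice,row,col) <-> physical (x,y,z))


def to_sitk_image(volume: VolumeImage) -> sitk.Image:
    img = sitk.GetImageFromArray(volume.data)
    sz, sy, sx = volume.spacing_mm
    img.SetSpacing((sx, sy, sz))
    # centre the physical frame on the grid so rotations pivot about the body
    shape = volume.data.shape  # (z, y, x)
    origin = [-(n - 1) / 2.0 * s for n, s in zip(shape[::-1], (sx, sy, sz))]
    img.SetOrigin(origin)
    return img


def _labels_to_sitk(mask: LabelMask) -> sitk.Image:
    img = sitk.GetImageFromArray(mask.labels.astype(np.int16))
    sz, sy, sx = mask.spacing_mm
    img.SetSpacing((sx, sy, sz))
    shape = mask.labels.shape
    origin = [-(n - 1) / 2.0 * s for n, s in zip(shape[::-1], (sx, sy, sz))]
    img.SetOrigin(origin)
    return img


def resample_volume(
    moving: VolumeImage,
    transform: RigidTransform,
    reference: VolumeImage,
    default_value: float = 0.0,
) -> VolumeImage:
    """Resample ``moving`` onto ``reference``'s grid with linear interpolation.

    ``transform`` maps reference-grid points into ``moving``'s space (the
    usual pull-back resampling convention).
    """
    out = sitk.Resample(
        to_sitk_image(moving),
        to_sitk_image(reference),
        transform.to_sitk(),
        sitk.sitkLinear,
        float(default_value),
        sitk.sitkFloat64,
    )
    data = np.clip(sitk.GetArrayFromImage(out), 0.0, None)
    return VolumeImage(data, reference.spacing_mm)


def resample_mask(mask: LabelMask, transform: RigidTransform) -> LabelMask:
    """Nearest-neighbour resampling of a categorical label grid."""
    ref = _labels_to_sitk(mask)
    out = sitk.Resample(
        _labels_to_sitk(mask),
        ref,
        transform.to_sitk(),
        sitk.sitkNearestNeighbor,
        0.0,
        sitk.sitkInt16,
    )
    return LabelMask(
        sitk.GetArrayFromImage(out).astype(np.int16),
        dict(mask.label_names),
        mask.spacing_mm,
    )


# ---------------------------------------------------------------------------
# Registration and template building


def register_rigid(
    moving: VolumeImage, fixed: VolumeImage, iterations: int = 200
) -> RigidTransform:
    """Estimate the rigid transform mapping ``fixed`` points to ``moving``.

    Mean-squares metric, full sampling, regular-step gradient descent with
    parameter scales from physical shift.  Both images are divided by the
    fixed image's mean intensity so the metric magnitude (and therefore the
    optimizer path) does not depend on the global intensity scale.
    """
    norm = float(fixed.data.mean())
    if norm <= 0:
        raise ValueError("registration failure: fixed image has no signal")
    f_img = to_sitk_image(VolumeImage(fixed.data / norm, fixed.spacing_mm))
    m_img = to_sitk_image(VolumeImage(moving.data / norm, moving.spacing_mm))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    init = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )
    reg.SetInitialTransform(sitk.Euler3DTransform(init), inPlace=True)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-9,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    final = sitk.Euler3DTransform(reg.Execute(f_img, m_img))
    return RigidTransform.from_sitk(final, convention="fixed_to_moving")


def register_visit_to_template(
    visit: VolumeImage, template: VolumeImage
) -> RigidTransform:
    """Rigid transform mapping visit-space points to template-space points."""
    t = register_rigid(moving=visit, fixed=template)  # template -> visit
    out = t.inverse()
    out.convention = "visit_to_template"
    return out


def _border_background(volume: VolumeImage) -> float:
    d = volume.data
    border = np.concatenate(
        [d[0].ravel(), d[-1].ravel(), d[:, 0].ravel(), d[:, -1].ravel(),
         d[:, :, 0].ravel(), d[:, :, -1].ravel()]
    )
    return float(np.median(border))


def build_template(
    visits: list[VolumeImage], iterations: int = 2
) -> tuple[VolumeImage, list[RigidTransform]]:
    """Within-subject average template and per-visit rigid transforms.

    Iterative scheme: starting from the first visit as the provisional
    template, each visit is registered to the current template, all visits
    are averaged in template space, and the procedure repeats a fixed small
    number of iterations.  With a single visit, the template is that visit
    and the transform is the identity.  Returned transforms map visit space
    to template space.
    """
    if not visits:
        raise ValueError("at least one visit is required")
    shapes = {v.shape for v in visits}
    if len(shapes) > 1:
        raise ValueError(f"all visits must share one grid, got shapes {shapes}")
    if len(visits) == 1:
        v = visits[0]
        return VolumeImage(v.data.copy(), v.spacing_mm), [RigidTransform.identity()]

    template = visits[0]
    transforms = [RigidTransform.identity() for _ in visits]
    for _ in range(iterations):
        transforms = [register_visit_to_template(v, template) for v in visits]
        warped = [
            resample_volume(
                v, t.inverse(), reference=template, default_value=_border_background(v)
            )
            for v, t in zip(visits, transforms)
        ]
        template = VolumeImage(
            np.mean([w.data for w in warped], axis=0), template.spacing_mm
        )
    return template, transforms


def propagate_masks(
    template_mask: LabelMask, transforms: list[RigidTransform]
) -> list[LabelMask]:
    """Resample a template-space mask into each visit's space.

    ``transforms`` map visit space to template space; resampling a visit
    grid therefore pulls labels back through each transform directly, with
    nearest-neighbour interpolation (labels are categorical).
    """
    out = []
    for t in transforms:
        if t.convention not in ("visit_to_template", "fixed_to_moving"):
            raise ValueError(
                f"expected visit-to-template transforms, got {t.convention!r}"
            )
        out.append(resample_mask(template_mask, t))
    return out


# ---------------------------------------------------------------------------
# Bias field


@dataclass
class BiasField:
    """Smooth multiplicative field aligned to a volume, mean 1 over the fit region."""

    field: np.ndarray
    order: int

    def __post_init__(self) -> None:
        if np.any(self.field <= 0):
            raise ValueError("bias field must be strictly positive everywhere")


def _design_matrix(u: np.ndarray, v: np.ndarray, order: int) -> np.ndarray:
    cols = [np.ones_like(u), u, v]
    if order >= 2:
        cols += [u * u, u * v, v * v]
    return np.stack(cols, axis=-1)


def estimate_bias(
    volume: VolumeImage,
    mask: LabelMask,
    fit_labels=None,
    order: int = 2,
    per_label_intercepts: bool = True,
) -> BiasField:
    """Fit an in-plane polynomial shading field to log intensities.

    The fit region is the union of ``fit_labels`` (default: every
    non-background voxel).  With ``per_label_intercepts`` (default) the
    regression carries one intercept per label class in the region, so
    genuine mean-intensity differences between tissues or compartments are
    absorbed by the intercepts and only the shared smooth spatial trend is
    attributed to coil shading.  The field is shared across slices,
    exponentiated from the fitted log-polynomial, and normalized to mean 1
    over the fit region, so dividing by it preserves the region's mean
    intensity.
    """
    check_aligned(volume, mask)
    if fit_labels is None:
        fit_labels = [n for n in mask.label_names if n != "background"]
    region = mask.region(fit_labels)
    if not region.any():
        raise ValueError("bias fit region is empty")

    nz, ny, nx = volume.shape
    y_idx, x_idx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    u = (x_idx - (nx - 1) / 2.0) / max(nx / 2.0, 1.0)
    v = (y_idx - (ny - 1) / 2.0) / max(ny / 2.0, 1.0)
    X_plane = _design_matrix(u, v, order)  # (ny, nx, 1 + p)

    uu = np.broadcast_to(u, volume.shape)[region]
    vv = np.broadcast_to(v, volume.shape)[region]
    X_poly = _design_matrix(uu, vv, order)[:, 1:]  # drop global intercept
    lab_region = mask.labels[region]
    if per_label_intercepts:
        codes = np.unique(lab_region)
        dummies = (lab_region[:, None] == codes[None, :]).astype(float)
    else:
        dummies = np.ones((lab_region.size, 1))
    X_fit = np.concatenate([dummies, X_poly], axis=1)
    y_fit = np.log(np.clip(volume.data[region], 1e-12, None))
    beta, _, rank, _ = np.linalg.lstsq(X_fit, y_fit, rcond=None)
    if rank < X_fit.shape[1]:
        raise ValueError("degenerate bias fit: design matrix is rank deficient")

    beta_poly = beta[dummies.shape[1]:]
    log_plane = X_plane[..., 1:] @ beta_poly  # (ny, nx)
    field = np.exp(np.broadcast_to(log_plane, volume.shape))
    field = field / field[region].mean()
    return BiasField(field, order)


def correct_bias(volume: VolumeImage, field: BiasField) -> VolumeImage:
    """Divide out a multiplicative bias field."""
    if field.field.shape != volume.shape:
        raise ValueError("bias field shape does not match volume")
    return VolumeImage(volume.data / field.field, volume.spacing_mm)
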