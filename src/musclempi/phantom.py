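"""Longitudinal digital thigh phantom.

Generates axial T1-weighted-like volumes of both thighs with per-voxel
anatomical labels, a known fat-infiltration trajectory per muscle
compartment, a smooth multiplicative coil-bias field, additive noise,
rigid inter-visit misalignment, and clinical scores monotonically linked
to infiltration.  Everything applied is retained as ground truth so each
pipeline stage can be checked against an oracle.

Intensity model
---------------
On T1-weighted images fat (and fatty femoral marrow) is bright and muscle
dark.  Each muscle voxel is a partial-volume mixture
``(1 - w) * mu_muscle + w * mu_fat`` with the infiltration weight ``w``
drawn from a Beta distribution whose mean follows the compartment's
trajectory ``f(t) = clip(f0 + rate * t, 0, 1)``.  A small concentration
(default 0.5) yields the U-shaped weight distribution that produces the
characteristic bimodal muscle/fat intensity histogram.  The per-voxel Beta
draws share one latent uniform across visits (a copula), so infiltration
is spatially persistent over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .preprocess import RigidTransform, resample_mask, resample_volume
from .volio import (
    CANONICAL_LABELS,
    CLINICAL_COLUMNS,
    MUSCLE_ROIS,
    LabelMask,
    VolumeImage,
)

ROI_KEYS = ("right_ant", "right_post", "left_ant", "left_post")
_ROI_TO_LABEL = {
    "right_ant": "muscle_ant_R",
    "right_post": "muscle_post_R",
    "left_ant": "muscle_ant_L",
    "left_post": "muscle_post_L",
}


def _as_roi_dict(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [k for k in ROI_KEYS if k not in value]
        if missing:
            raise ValueError(f"per-ROI value missing entries for {missing}")
        return {k: float(value[k]) for k in ROI_KEYS}
    return {k: float(value) for k in ROI_KEYS}


@dataclass
class PhantomParams:
    """Geometry, intensity and trajectory parameters of one synthetic subject.

    Geometry defaults follow a 400 mm field of view reconstructed here on a
    coarse 64 x 64 in-plane grid with 4 mm slices and a 2 mm gap (slice
    pitch 6 mm).  Intensity means are arbitrary scanner units chosen so the
    marrow-normalized muscle mode sits near 30, the regime of healthy
    control MPI.
    """

    grid_shape: tuple[int, int, int] = (10, 64, 64)  # (slice, row, col)
    fov_mm: float = 400.0
    slice_thickness_mm: float = 4.0
    slice_gap_mm: float = 2.0
    thigh_radius_mm: float = 80.0
    subcut_thickness_mm: float = 18.0
    femur_radius_mm: float = 24.0
    marrow_radius_mm: float = 15.0
    thigh_offset_mm: float = 95.0  # thigh centres at +/- offset from midline
    mu_muscle: float = 150.0
    mu_fat: float = 500.0
    mu_marrow: float = 500.0
    mu_bone: float = 60.0
    mu_background: float = 20.0
    sigma_noise: float = 8.0
    bias_amplitude: float = 0.1
    bias_model: str = "poly2"  # "poly2" | "gaussian" | "none"
    f0_by_roi: dict[str, float] = field(
        default_factory=lambda: {
            "right_ant": 0.075,
            "right_post": 0.22,
            "left_ant": 0.06,
            "left_post": 0.25,
        }
    )
    rate_by_roi: dict[str, float] = field(
        default_factory=lambda: {
            "right_ant": 0.010,
            "right_post": 0.014,
            "left_ant": 0.008,
            "left_post": 0.016,
        }
    )
    beta_concentration: float | None = 0.5  # None -> deterministic w = f(t)
    # spatial correlation of the infiltration texture, voxels per axis
    # (slice, row, col); fatty replacement is patchy, not voxel-independent
    w_smooth_sigma_vox: tuple[float, float, float] = (0.5, 1.0, 1.0)
    mask_margin_voxels: int = 1
    misalign_mm: float = 3.0
    misalign_deg: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.w_smooth_sigma_vox = tuple(float(s) for s in self.w_smooth_sigma_vox)
        self.f0_by_roi = _as_roi_dict(self.f0_by_roi)
        self.rate_by_roi = _as_roi_dict(self.rate_by_roi)
        if not (self.marrow_radius_mm < self.femur_radius_mm < self.thigh_radius_mm):
            raise ValueError(
                "geometry requires marrow_radius_mm < femur_radius_mm < thigh_radius_mm"
            )
        if not (self.mu_bone < self.mu_muscle < self.mu_fat):
            raise ValueError("intensities must satisfy mu_bone < mu_muscle < mu_fat")
        if abs(self.mu_marrow - self.mu_fat) > 0.05 * self.mu_fat:
            raise ValueError("mu_marrow must lie within 5% of mu_fat (marrow is fatty)")
        for k, v in self.f0_by_roi.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"f0_by_roi[{k!r}] must be in [0, 1], got {v}")

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        in_plane = self.fov_mm / self.grid_shape[1]
        return (self.slice_thickness_mm + self.slice_gap_mm, in_plane, in_plane)

    def f_at(self, t_years: float) -> dict[str, float]:
        """Target infiltration fraction per compartment at time ``t``."""
        return {
            k: float(np.clip(self.f0_by_roi[k] + self.rate_by_roi[k] * t_years, 0.0, 1.0))
            for k in ROI_KEYS
        }


@dataclass
class GroundTruth:
    """Everything the generator applied, retrievable for oracle tests."""

    f_target_by_roi: dict[str, float]  # f(t) the Beta means were set to
    f_applied_by_roi: dict[str, float]  # empirical mean of w over each ROI
    w_field: np.ndarray  # per-voxel infiltration weight, template space
    template_labels: LabelMask  # label mask in template (unmoved) space
    applied_bias_field: np.ndarray | None
    applied_transform: RigidTransform  # visit space -> template space
    t_years: float


@dataclass
class ClinicalRecord:
    """Clinical scores for one subject-visit."""

    subject_id: str
    visit_index: int
    visit_time_years: float
    mrc_right_thigh: float  # 0-10 (knee flexion + extension)
    mrc_left_thigh: float  # 0-10
    css: float  # 0-5, half points allowed
    mfm_d1_pct: float
    mfm_d2_pct: float
    mfm_d3_pct: float
    mfm_total_pct: float
    bmi: float | None = None
    d4z4_ru: int | None = None

    @property
    def mrcs(self) -> float:
        """MRC sum score over both thighs (0-20)."""
        return self.mrc_right_thigh + self.mrc_left_thigh

    def as_row(self) -> dict:
        row = {c: getattr(self, c, None) for c in CLINICAL_COLUMNS if c != "mrcs"}
        row["mrcs"] = self.mrcs
        return {c: row[c] for c in CLINICAL_COLUMNS}


# ---------------------------------------------------------------------------
# Geometry and fields


def _grid_coords(params: PhantomParams):
    """Physical (z, y, x) coordinate arrays, mm, centred on the grid."""
    nz, ny, nx = params.grid_shape
    sz, sy, sx = params.spacing_mm
    z = (np.arange(nz) - (nz - 1) / 2.0) * sz
    y = (np.arange(ny) - (ny - 1) / 2.0) * sy
    x = (np.arange(nx) - (nx - 1) / 2.0) * sx
    return np.meshgrid(z, y, x, indexing="ij")


_LABEL_CACHE: dict[tuple, np.ndarray] = {}


def _geometry_key(params: PhantomParams) -> tuple:
    return (
        params.grid_shape,
        params.fov_mm,
        params.slice_thickness_mm,
        params.slice_gap_mm,
        params.thigh_radius_mm,
        params.subcut_thickness_mm,
        params.femur_radius_mm,
        params.marrow_radius_mm,
        params.thigh_offset_mm,
        params.mask_margin_voxels,
    )


def build_labels(params: PhantomParams) -> LabelMask:
    """Template-space anatomical label partition.

    Two mirrored thigh cylinders, each with a subcutaneous fat ring,
    anterior/posterior muscle compartments, cortical bone and a marrow
    lumen.  Muscle voxels within ``mask_margin_voxels`` (in-plane) of a
    non-muscle interface are relabelled ``muscle_margin``.
    """
    key = _geometry_key(params)
    cached = _LABEL_CACHE.get(key)
    if cached is not None:
        return LabelMask(cached.copy(), dict(CANONICAL_LABELS), params.spacing_mm)
    zz, yy, xx = _grid_coords(params)
    labels = np.zeros(params.grid_shape, dtype=np.int16)
    r_muscle_outer = params.thigh_radius_mm - params.subcut_thickness_mm
    if r_muscle_outer <= params.femur_radius_mm:
        raise ValueError("subcutaneous ring leaves no room for muscle")
    half_fov = params.fov_mm / 2.0
    if params.thigh_offset_mm + params.thigh_radius_mm > half_fov:
        raise ValueError(
            "grid too small to contain thigh geometry: "
            f"offset {params.thigh_offset_mm} + radius {params.thigh_radius_mm} "
            f"exceeds half field of view {half_fov}"
        )

    for side, sign in (("R", -1.0), ("L", 1.0)):
        cx = sign * params.thigh_offset_mm
        r = np.hypot(xx - cx, yy)
        anterior = yy < 0
        in_thigh = r <= params.thigh_radius_mm
        in_muscle = r <= r_muscle_outer
        in_bone = r <= params.femur_radius_mm
        in_marrow = r <= params.marrow_radius_mm
        labels[in_thigh] = CANONICAL_LABELS["subcut_fat"]
        labels[in_muscle & anterior] = CANONICAL_LABELS[f"muscle_ant_{side}"]
        labels[in_muscle & ~anterior] = CANONICAL_LABELS[f"muscle_post_{side}"]
        labels[in_bone] = CANONICAL_LABELS[f"cortical_bone_{side}"]
        labels[in_marrow] = CANONICAL_LABELS[f"marrow_{side}"]

    if params.mask_margin_voxels > 0:
        structure = np.zeros((1, 3, 3), dtype=bool)
        structure[0] = True  # in-plane 8-neighbourhood
        muscle_codes = [CANONICAL_LABELS[n] for n in MUSCLE_ROIS]
        muscle_all = np.isin(labels, muscle_codes)
        interior = ndimage.binary_erosion(
            muscle_all, structure=structure, iterations=params.mask_margin_voxels
        )
        labels[muscle_all & ~interior] = CANONICAL_LABELS["muscle_margin"]
        # conservative marrow delineation: keep only the lumen interior,
        # give the boundary ring to cortical bone
        for side in "RL":
            marrow = labels == CANONICAL_LABELS[f"marrow_{side}"]
            lumen = ndimage.binary_erosion(
                marrow, structure=structure, iterations=params.mask_margin_voxels
            )
            labels[marrow & ~lumen] = CANONICAL_LABELS[f"cortical_bone_{side}"]
        # conservative subcutaneous-fat delineation (it anchors the bias
        # fit): keep the ring interior, move boundary voxels to fat_margin
        subcut = labels == CANONICAL_LABELS["subcut_fat"]
        ring_interior = ndimage.binary_erosion(
            subcut, structure=structure, iterations=params.mask_margin_voxels
        )
        labels[subcut & ~ring_interior] = CANONICAL_LABELS["fat_margin"]

    if len(_LABEL_CACHE) > 16:
        _LABEL_CACHE.clear()
    _LABEL_CACHE[key] = labels.copy()
    return LabelMask(labels, dict(CANONICAL_LABELS), params.spacing_mm)


def _margin_compartments(params: PhantomParams) -> np.ndarray:
    """Compartment assignment including margin voxels (pre-erosion labels)."""
    return build_labels(replace(params, mask_margin_voxels=0)).labels


def build_bias_field(params: PhantomParams) -> np.ndarray | None:
    """Smooth in-plane multiplicative shading, shared across slices.

    Peak relative deviation equals ``bias_amplitude``; the field is
    normalized to mean 1 over the body (non-background) region.
    """
    if params.bias_amplitude == 0 or params.bias_model == "none":
        return None
    _, yy, xx = _grid_coords(params)
    u = xx / (params.fov_mm / 2.0)
    v = yy / (params.fov_mm / 2.0)
    if params.bias_model == "poly2":
        p = 0.6 * u + 0.8 * v - 0.5 * u**2 - 0.3 * u * v + 0.4 * v**2
    elif params.bias_model == "gaussian":
        p = np.exp(-((u - 0.4) ** 2 + (v - 0.3) ** 2) / (2 * 0.5**2))
    else:
        raise ValueError(f"unknown bias_model {params.bias_model!r}")
    p = p / np.max(np.abs(p))
    fld = 1.0 + params.bias_amplitude * p
    body = build_labels(params).labels != CANONICAL_LABELS["background"]
    fld = fld / fld[body].mean()
    return fld


def _latent_uniform(params: PhantomParams) -> np.ndarray:
    """Per-voxel latent uniforms shared across visits (infiltration copula).

    A Gaussian random field with short-range spatial correlation is mapped
    through the normal CDF, so the per-voxel marginal stays uniform while
    infiltrated tissue forms contiguous patches.
    """
    rng = np.random.default_rng([int(params.seed), 7919])
    g = rng.standard_normal(size=params.grid_shape)
    if any(s > 0 for s in params.w_smooth_sigma_vox):
        g = ndimage.gaussian_filter(g, sigma=params.w_smooth_sigma_vox, mode="wrap")
        g = g / g.std()
    from scipy.special import ndtr

    return ndtr(g)


def _w_field(params: PhantomParams, t_years: float, latent: np.ndarray) -> np.ndarray:
    """Infiltration weight per anatomical-muscle voxel (0 elsewhere)."""
    comp = _margin_compartments(params)
    w = np.zeros(params.grid_shape, dtype=np.float64)
    f_t = params.f_at(t_years)
    for roi in ROI_KEYS:
        sel = comp == CANONICAL_LABELS[_ROI_TO_LABEL[roi]]
        f = f_t[roi]
        if params.beta_concentration is None or f in (0.0, 1.0):
            w[sel] = f
        else:
            a = f * params.beta_concentration
            b = (1.0 - f) * params.beta_concentration
            w[sel] = stats.beta.ppf(latent[sel], a, b)
    return w


def _draw_misalignment(params: PhantomParams, rng: np.random.Generator) -> RigidTransform:
    """Rigid inter-visit repositioning: mostly in-plane, small through-plane."""
    t_in = rng.uniform(-params.misalign_mm, params.misalign_mm, size=2)
    t_z = rng.uniform(-0.3 * params.misalign_mm, 0.3 * params.misalign_mm)
    r_z = rng.uniform(-params.misalign_deg, params.misalign_deg)
    r_xy = rng.uniform(-0.25 * params.misalign_deg, 0.25 * params.misalign_deg, size=2)
    return RigidTransform(
        rotation_deg=(float(r_xy[0]), float(r_xy[1]), float(r_z)),
        translation_mm=(float(t_in[0]), float(t_in[1]), float(t_z)),
        center_mm=(0.0, 0.0, 0.0),
    )


def generate_timepoint(
    params: PhantomParams,
    t_years: float,
    misalign: RigidTransform | None = None,
) -> tuple[VolumeImage, LabelMask, GroundTruth]:
    """Generate one visit of one subject.

    Returns the (possibly misaligned) volume, the label mask in the moved
    visit space, and the ground truth (template-space labels and weights,
    applied bias, applied transform).  For ``t_years == 0`` the subject is
    in template space and the transform is the identity; for later visits a
    rigid misalignment is drawn (or taken from ``misalign``).
    """
    if t_years < 0:
        raise ValueError("t_years must be >= 0")
    template_labels = build_labels(params)
    comp = _margin_compartments(params)
    latent = _latent_uniform(params)
    w = _w_field(params, t_years, latent)

    # intensities follow the anatomy (pre-margin labels); the margined
    # template_labels only define what the analysis masks select
    ideal = np.full(params.grid_shape, params.mu_background, dtype=np.float64)
    lab = template_labels.labels
    ideal[comp == CANONICAL_LABELS["subcut_fat"]] = params.mu_fat
    for side in "RL":
        ideal[comp == CANONICAL_LABELS[f"cortical_bone_{side}"]] = params.mu_bone
        ideal[comp == CANONICAL_LABELS[f"marrow_{side}"]] = params.mu_marrow
    muscle_any = np.isin(
        comp, [CANONICAL_LABELS[_ROI_TO_LABEL[r]] for r in ROI_KEYS]
    )
    ideal[muscle_any] = (1.0 - w[muscle_any]) * params.mu_muscle + w[
        muscle_any
    ] * params.mu_fat

    bias = build_bias_field(params)
    signal = ideal if bias is None else ideal * bias

    rng_visit = np.random.default_rng(
        [int(params.seed), 104729, int(round(t_years * 1e6))]
    )
    if params.sigma_noise > 0:
        signal = signal + rng_visit.normal(0.0, params.sigma_noise, size=signal.shape)
        signal = np.clip(signal, 0.0, None)

    spacing = params.spacing_mm
    if t_years > 0:
        transform = misalign if misalign is not None else _draw_misalignment(params, rng_visit)
    else:
        transform = RigidTransform.identity()
    if not transform.is_identity():
        vol = VolumeImage(signal, spacing)
        moved = resample_volume(vol, transform, reference=vol, default_value=params.mu_background)
        moved_labels = resample_mask(template_labels, transform)
        volume, visit_labels = moved, moved_labels
    else:
        volume = VolumeImage(signal, spacing)
        visit_labels = LabelMask(lab.copy(), dict(CANONICAL_LABELS), spacing)

    f_applied = {}
    for roi in ROI_KEYS:
        sel = lab == CANONICAL_LABELS[_ROI_TO_LABEL[roi]]
        f_applied[roi] = float(w[sel].mean())
    truth = GroundTruth(
        f_target_by_roi=params.f_at(t_years),
        f_applied_by_roi=f_applied,
        w_field=w,
        template_labels=template_labels,
        applied_bias_field=bias,
        applied_transform=transform,
        t_years=float(t_years),
    )
    return volume, visit_labels, truth


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class CohortDistribution:
    """Across-subject distribution of phantom parameters and clinical noise.

    Infiltration levels and progression rates are log-normal across
    subjects (strictly positive, right-skewed, as in patient cohorts), with
    fixed compartment factors reproducing the anterior/posterior and
    right/left asymmetry of thigh involvement.  Clinical noise SDs set how
    loosely the scores track infiltration; zero noise gives an exact
    monotone link.
    """

    f0_median: float = 0.14
    f0_log_sigma: float = 1.0
    f0_max: float = 0.95
    roi_f_factors: dict[str, float] = field(
        default_factory=lambda: {
            "right_ant": 0.55,
            "right_post": 1.45,
            "left_ant": 0.50,
            "left_post": 1.60,
        }
    )
    roi_f_jitter_sigma: float = 0.25
    rate_median: float = 0.0125
    rate_log_sigma: float = 1.0  # wide spread: per-patient annual rates span ~two decades
    roi_rate_jitter_sigma: float = 0.3
    visit_time_jitter_years: float = 0.04
    mrc_noise_sd: float = 2.2  # per thigh
    css_noise_sd: float = 0.45
    mfm_noise_sd: float = 4.0
    clinical_noise_scale: float = 1.0  # 0 -> exact monotone link


@dataclass
class SubjectData:
    subject_id: str
    params: PhantomParams
    visit_times: list[float]
    volumes: list[VolumeImage]
    masks: list[LabelMask]  # visit-space masks as returned by the generator
    truths: list[GroundTruth]
    clinical: list[ClinicalRecord]


@dataclass
class Cohort:
    subjects: list[SubjectData]
    distribution: CohortDistribution
    seed: int

    def clinical_table(self) -> pd.DataFrame:
        rows = [rec.as_row() for s in self.subjects for rec in s.clinical]
        return pd.DataFrame(rows, columns=list(CLINICAL_COLUMNS))


def _draw_subject_params(
    base: PhantomParams, dist: CohortDistribution, rng: np.random.Generator, seed: int
) -> PhantomParams:
    f_base = min(dist.f0_max, float(np.exp(rng.normal(np.log(dist.f0_median), dist.f0_log_sigma))))
    r_base = float(np.exp(rng.normal(np.log(dist.rate_median), dist.rate_log_sigma)))
    f0, rate = {}, {}
    for roi in ROI_KEYS:
        jf = float(np.exp(rng.normal(0.0, dist.roi_f_jitter_sigma)))
        jr = float(np.exp(rng.normal(0.0, dist.roi_rate_jitter_sigma)))
        f0[roi] = float(np.clip(f_base * dist.roi_f_factors[roi] * jf, 0.0, dist.f0_max))
        rate[roi] = r_base * dist.roi_f_factors[roi] * jr
    return replace(base, f0_by_roi=f0, rate_by_roi=rate, seed=seed)


def _round_to(x: float, step: float) -> float:
    return float(np.round(x / step) * step)


def _clinical_for(
    subject_id: str,
    visit_index: int,
    t: float,
    params: PhantomParams,
    dist: CohortDistribution,
    rng: np.random.Generator,
    bmi: float,
    d4z4: int,
) -> ClinicalRecord:
    """Monotone infiltration -> score link plus independent noise.

    MRC per thigh decreases linearly in the thigh-mean infiltration, CSS
    increases with the square root of whole-thigh infiltration (steep early,
    saturating), and MFM dimensions decrease with dimension-specific slopes
    (proximal D1 most affected, distal D3 least).  With zero clinical noise
    the latent continuous scores are returned unrounded, so the link is
    exactly monotone; with noise they are rounded to the instrument's
    granularity (integer MRC, half-point CSS, 0.1% MFM).
    """
    f = params.f_at(t)
    f_r = (f["right_ant"] + f["right_post"]) / 2.0
    f_l = (f["left_ant"] + f["left_post"]) / 2.0
    f_mean = (f_r + f_l) / 2.0
    scale = dist.clinical_noise_scale

    def noisy(x, sd, lo, hi, step):
        if scale == 0:
            return float(np.clip(x, lo, hi))
        x = x + rng.normal(0.0, sd * scale)
        return float(np.clip(_round_to(x, step), lo, hi))

    mrc_r = noisy(10.0 * (1.0 - f_r), dist.mrc_noise_sd, 0.0, 10.0, 1.0)
    mrc_l = noisy(10.0 * (1.0 - f_l), dist.mrc_noise_sd, 0.0, 10.0, 1.0)
    css = noisy(7.5 * np.sqrt(f_mean), dist.css_noise_sd, 0.0, 5.0, 0.5)
    d1 = noisy(100.0 * (1.0 - 0.9 * f_mean), dist.mfm_noise_sd, 0.0, 100.0, 0.1)
    d2 = noisy(100.0 * (1.0 - 0.10 * f_mean), 0.5 * dist.mfm_noise_sd, 0.0, 100.0, 0.1)
    d3 = noisy(100.0 * (1.0 - 0.05 * f_mean), 0.5 * dist.mfm_noise_sd, 0.0, 100.0, 0.1)
    total = noisy(100.0 * (1.0 - 0.45 * f_mean), dist.mfm_noise_sd, 0.0, 100.0, 0.1)
    return ClinicalRecord(
        subject_id=subject_id,
        visit_index=visit_index,
        visit_time_years=float(t),
        mrc_right_thigh=mrc_r,
        mrc_left_thigh=mrc_l,
        css=css,
        mfm_d1_pct=d1,
        mfm_d2_pct=d2,
        mfm_d3_pct=d3,
        mfm_total_pct=total,
        bmi=bmi,
        d4z4_ru=d4z4,
    )


def generate_cohort(
    n_subjects: int,
    visit_times: Sequence[float],
    params_distribution: CohortDistribution | None = None,
    seed: int = 0,
    base_params: PhantomParams | None = None,
) -> Cohort:
    """Generate a longitudinal cohort with linked clinical scores.

    ``visit_times`` are nominal decimal years, strictly increasing from 0;
    each subject's actual follow-up times are jittered by the distribution's
    ``visit_time_jitter_years`` (visit 0 stays at 0).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    visit_times = [float(t) for t in visit_times]
    if not visit_times:
        raise ValueError("visit_times must not be empty")
    if visit_times[0] != 0.0 or any(
        b <= a for a, b in zip(visit_times, visit_times[1:])
    ):
        raise ValueError("visit_times must be strictly increasing and start at 0")
    dist = params_distribution or CohortDistribution()
    base = base_params or PhantomParams()
    rng = np.random.default_rng([int(seed), 9176])

    subjects = []
    for i in range(n_subjects):
        sid = f"sub-{i + 1:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        params = _draw_subject_params(base, dist, rng, sub_seed)
        bmi = float(np.round(rng.normal(24.0, 3.0), 1))
        f_mean0 = float(np.mean(list(params.f0_by_roi.values())))
        d4z4 = int(np.clip(round(9.0 - 6.0 * f_mean0 + rng.normal(0.0, 1.5)), 1, 10))
        times = [
            t if j == 0 else max(
                0.05, t + rng.uniform(-dist.visit_time_jitter_years, dist.visit_time_jitter_years)
            )
            for j, t in enumerate(visit_times)
        ]
        volumes, masks, truths, clinical = [], [], [], []
        for j, t in enumerate(times):
            vol, msk, truth = generate_timepoint(params, t)
            volumes.append(vol)
            masks.append(msk)
            truths.append(truth)
            clinical.append(
                _clinical_for(sid, j, t, params, dist, rng, bmi, d4z4)
            )
        subjects.append(
            SubjectData(sid, params, times, volumes, masks, truths, clinical)
        )
    return Cohort(subjects, dist, int(seed))
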