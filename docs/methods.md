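# Methods

## The MPI biomarker

`musclempi` quantifies fatty degeneration of thigh muscle on
T1-weighted MRI with the **mean pixel intensity** (MPI): the sum of
normalized voxel intensities over a muscle region of interest divided by
the voxel count.  On T1-weighted images fat is bright and muscle dark, so
MPI rises both when fat replaces muscle tissue within the ROI and when the
muscle compartment shrinks relative to residual bright tissue.  Unlike
threshold-based fat-fraction indices, MPI uses the entire intensity
distribution and requires no muscle/fat cutoff.

Intensities are put on a subject-independent scale by mapping the fatty
marrow in the femoral lumen — the brightest stable reference tissue in the
field of view — to 100%, via the two-point linear map `0 -> 0`,
`reference -> 100`.  The reference statistic is the **median** over pooled
left+right marrow voxels (robust to cortical-bone partial volume at the
lumen boundary); the mean is available behind a configuration switch.
Values above 100 are deliberately not clipped.  Because the map is linear
through the origin, every downstream MPI is invariant to a global rescaling
of the raw image — the property that makes MPI comparable across sessions
and subjects at a fixed field strength.

With the normalized muscle mode at `m` (≈30 with the default phantom
intensities) and ROI fat fraction `f`, the mixture model implies the
closed form `MPI = m + (100 - m) * f`, which the test suite uses as an
oracle.

## Processing pipeline

Per subject, visits are processed in four stages:

1. **Within-subject template.** All visits are rigidly registered
   (mean-squares metric, full voxel sampling, regular-step gradient
   descent) and averaged; two fixed iterations of register-and-average are
   used.  Rigid motion is exactly invertible and matches the phantom's
   inter-visit motion model; nonlinear registration of real anatomy is
   deliberately out of scope.
2. **Template-space masks.** Compartment masks (right/left x
   anterior/posterior, femur, marrow) are defined once in template space —
   for the phantom they come from the generator's ground truth; for real
   data they would be drawn manually on the template.
3. **Mask propagation.** Template masks are resampled into each visit's
   space through the inverse transforms with nearest-neighbour
   interpolation (labels are categorical).
4. **Bias correction, normalization, MPI.** Each visit is corrected for
   residual receive-coil shading, normalized to the marrow reference and
   reduced to MPI per compartment, per thigh, per anterior/posterior
   grouping and over both thighs.  Pooled MPIs pool the voxels themselves
   (voxel-count-weighted means), matching the "sum over pixels / number of
   pixels" definition; MPI is computed from voxels, never from binned
   histograms, to avoid discretization bias.

### Bias correction

Shading is modelled as a smooth multiplicative in-plane field, shared
across slices: an order-2 polynomial fitted by least squares to log
intensities, exponentiated, and normalized to mean 1 over the fit region.
Two design points matter in practice:

* The regression carries **one intercept per label class**, so genuine
  mean-intensity differences between tissues are absorbed by the
  intercepts and only the shared smooth trend is attributed to shading.
* The default fit region is **homogeneous bright tissue** (the
  subcutaneous fat ring plus the marrow lumina).  Fitting on muscle is
  statistically poor: the bimodal muscle/fat texture has a log-intensity
  SD of ~0.5, and its regression noise projects onto smooth fields with
  compartment-scale structure that would corrupt MPI by several percent.

This is an explicit, testable replacement for N4; full N4 fidelity is out
of scope.

## The synthetic thigh phantom

The phantom emulates an axial T1-weighted acquisition of both thighs
(400 mm field of view, 4 mm slices with a 2 mm gap; the default grid is
64 x 64 in-plane, i.e. 6.25 mm pixels — coarser than a scanner but
preserving every geometric relationship).  Each thigh is a cylinder with a
subcutaneous fat ring, anterior/posterior muscle compartments, cortical
bone, and a fatty marrow lumen.  Default intensity means (muscle 150,
fat/marrow 500, bone 60, background 20, arbitrary units) put the
normalized muscle mode at 30, the regime of healthy-control MPI (~30).

**Infiltration model.** Each muscle voxel is a partial-volume mixture
`(1 - w) mu_muscle + w mu_fat`.  `w` follows a Beta distribution with mean
`f(t) = clip(f0 + rate * t, 0, 1)` per compartment and concentration 0.5;
the small concentration gives the U-shaped weight distribution that
produces the characteristic bimodal normalized-intensity histogram (muscle
mode near 30, fat mode near 100).  The per-voxel draws share one latent
Gaussian field across visits (a copula) with ~1 voxel in-plane correlation
length, so infiltration is patchy and spatially persistent over time — as
in real dystrophic muscle, and essential for longitudinal rate estimates
not to be dominated by texture redraw noise.  Setting the concentration to
`None` collapses `w` to `f(t)` exactly, the deterministic mode used by
closed-form oracles.

**Degradations.** A smooth multiplicative in-plane field (order-2
polynomial by default, peak relative deviation 0.1) emulates residual coil
shading; additive Gaussian noise (SD 8, i.e. SNR ~60 against fat) emulates
the high-SNR regime of a 1.5 T spin-echo acquisition — Rician noise is
deliberately not modelled, a negligible difference at this SNR; visits
after baseline are moved by a random rigid transform (up to 3 mm in-plane,
2 degrees about the slice axis, smaller through-plane components).  The
slice gap is modelled by slice-centre spacing only.

**Conservative delineation.** Muscle compartment labels are eroded by one
voxel from every non-muscle interface (the eroded ring keeps muscle tissue
intensity under the reserved label `muscle_margin`), and the marrow and
subcutaneous-fat labels are likewise eroded to their interiors.  This
mirrors how masks are drawn in practice — carefully avoiding the
subcutaneous fat — and makes the analysis robust to the partial-volume
blending that resampling introduces at tissue interfaces.

**Cohort model.** Across subjects, the baseline whole-thigh infiltration
is log-normal (median 0.14, log-SD 1.0, capped at 0.95) with fixed
compartment factors reproducing the anterior/posterior and right/left
asymmetry of involvement; progression rates are log-normal (median
0.0125/yr, log-SD 1.0 — per-patient annual MPI rates span roughly two
decades, matching published natural-history spread).  Clinical scores are
monotone functions of infiltration — MRC per thigh decreasing linearly,
CSS increasing with the square root (steep early, saturating), MFM
dimensions decreasing with dimension-specific slopes (D1 most, D3 least) —
plus independent Gaussian noise, then rounded to instrument granularity
(integer MRC, half-point CSS).  The MRC noise SD (2.2 per thigh) was
calibrated so the baseline Spearman correlation between MPI and the MRC
sum score centres near 0.66, the strength of association observed
clinically; with zero clinical noise the link is exactly monotone (a
generator-level oracle).

**What the phantom does not emulate.** Real anatomy (multiple muscles,
fascia, vessels, skin), nonlinear inter-visit deformation, through-plane
anatomy changes, chemical-shift artefacts, Rician noise, scanner drift,
and manual-segmentation variability.  Passing tests therefore demonstrate
correctness of the computational pipeline under a faithful intensity
model, not clinical performance on patient images.

## Longitudinal and statistical analysis

Rates of change are `(v2 - v1) / (t2 - t1)` in years, using each
subject's actual elapsed time; relative rates are
`[100 (last - first) / first] / years`.  Summaries are median (IQR)
throughout.  Severity stratification compares rate distributions between
CSS < 3 and CSS >= 3 with a two-sample rank test (a subject at exactly 3
is severe).

The nonparametric battery reports the conventions used in clinical
software: the signed-rank statistic V (sum of positive-difference ranks,
zero differences dropped — the hot path, since clinical scores often do
not change between visits; exact p for n <= 25 without ties, normal
approximation otherwise), Friedman chi-squared with k-1 df for three or
more visits, Spearman rho with mid-ranks, and Kruskal-Wallis with pairwise
rank-sum post-hocs under Bonferroni correction (the only multiplicity
adjustment applied, matching the protocol).  Significance is 0.05;
p-values are reported at full precision.

Test-retest agreement reports the mean absolute inter-scan difference M,
its SD, limits of agreement `M +/- 1.96 SD` (the Bland-Altman construction
applied to unsigned differences as in the source protocol; the signed
variant is available), a paired t test, and the intraclass correlation.
The ICC form is pinned to **ICC(A,1)** — two-way random effects, absolute
agreement, single measurement — because the same scanner and procedure are
used in both sessions and agreement, not consistency, is the question; the
variant is configurable where the choice matters.

## Numerical and design choices

* Axis order is `(slice, row, col)`, 0-based; physical units are mm;
  one convention end to end prevents silent transpositions.
* Registration uses full-sampling mean squares, so runs are deterministic;
  both images are pre-divided by the fixed image's mean so the optimizer
  path does not depend on the global intensity scale.
* Template building stops after 2 register-and-average iterations —
  converged for few-mm rigid misalignments and keeps runtime bounded.
* MPI pools voxels across slices of an ROI rather than averaging
  per-slice means; the difference vanishes for uniform slice coverage.
* All randomness derives from one root seed via per-purpose child streams
  (structure, per-visit noise, cohort draws); regeneration is
  bit-identical.
* Degenerate inputs fail loudly: empty ROIs and marrow masks, non-positive
  references, rank-deficient bias fits, zero-length follow-up intervals,
  constant inputs to rank correlation.

## Problem sizes

Default test and example problem sizes — 6–10 slices at 64 x 64 in-plane,
cohorts of 35 subjects with two visits — were chosen so a full cohort
analysis runs in minutes on a laptop while every ROI retains hundreds to
thousands of voxels; all reported properties (closed-form recovery, rate
recovery, agreement regimes) are stable at these sizes.

## Known limitations

* Rigid-only registration: appropriate for the phantom's motion model and
  within-subject thigh imaging, not for inter-subject analysis.
* The polynomial bias model cannot represent high-order or through-plane
  shading; the estimator's fit region must be reasonably homogeneous.
* Marrow referencing assumes fatty (yellow) marrow in the mid-femur and is
  not suitable where red marrow may be present (e.g. pediatric cohorts).
* MPI values are comparable only within one field strength and sequence.
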