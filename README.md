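# musclempi

Quantitative muscle-MRI analysis for slowly progressive myopathies such as
facioscapulohumeral muscular dystrophy (FSHD), built around the **mean
pixel intensity (MPI)** biomarker: the mean of marrow-normalized
T1-weighted voxel intensities over a thigh-muscle region of interest.
Because fat is bright and muscle dark on T1-weighted images, MPI rises
with both fat infiltration and muscle loss, making it a sensitive
longitudinal index where clinical scales (MRC, MFM, CSS) barely move over
a year.  The package is aimed at imaging scientists who want a tested,
fully reproducible reference implementation of the method — including a
synthetic longitudinal thigh phantom so every stage can be validated
without patient data.

## The method in brief

For a muscle ROI with voxel intensities `I_i` and a marrow reference
intensity `R` (median over the femoral lumen, mapped to 100%):

```
I'_i      = 100 * I_i / R                 (two-point normalization, no clipping)
MPI(ROI)  = (1/N) * sum_i I'_i           (pooled over all slices and voxels)
```

MPI is computed per compartment (right/left x anterior/posterior), per
thigh, and over both thighs (`MPI_total`).  Under the partial-volume
mixture model with normalized muscle mode `m`, `MPI = m + (100 - m) * f`
for ROI fat fraction `f`.  Longitudinal change is summarized as rates
`(v2 - v1)/(t2 - t1)` per year and annualized relative rates
`[100 (last - first)/first]/years`; test–retest reproducibility as
Bland–Altman limits `M ± 1.96 SD` of absolute inter-scan differences and
ICC(A,1).

The processing pipeline (per subject): rigid within-subject template
registration → template-space compartment masks → nearest-neighbour mask
propagation to each visit → polynomial bias correction → marrow
normalization → MPI.  See `docs/methods.md` for the model, parameter
defaults, and design rationale.

## Worked example

Simulate one subject with two visits ~12.5 months apart, run the full
pipeline, and report rates:

```python
from musclempi.phantom import PhantomParams, generate_timepoint
from musclempi.pipeline import process_subject
from musclempi.longitudinal import rate_of_change, relative_rate

p = PhantomParams(grid_shape=(6, 64, 64), seed=42)
visits = [generate_timepoint(p, t) for t in (0.0, 1.04)]
results = process_subject([v for v, _, _ in visits],
                          visits[0][2].template_labels, "sub-001")
for res, t in zip(results, (0.0, 1.04)):
    print(f"visit t={t:5.2f}y  MPI_total={res.mpi_total:6.2f}  "
          f"anterior={res.mpi_anterior:6.2f}  posterior={res.mpi_posterior:6.2f}")
m0, m1 = results[0].mpi_total, results[1].mpi_total
print(f"rate = {rate_of_change(m0, m1, 0.0, 1.04):.2f} MPI units/year")
print(f"relative rate = {relative_rate(m0, m1, 1.04):.2f} %/year")
```

prints

```
visit t= 0.00y  MPI_total= 40.64  anterior= 33.88  posterior= 47.41
visit t= 1.04y  MPI_total= 41.72  anterior= 35.31  posterior= 48.13
rate = 1.03 MPI units/year
relative rate = 2.54 %/year
```

This subject's posterior compartments are more infiltrated than the
anterior ones (true baseline fat fractions 0.17–0.33 vs 0.05–0.07), MPI
sits in the patient range (high 30s to 40s against ~30 for healthy
muscle), and the annualized relative increase of ~2.5 %/year is the
regime reported for FSHD natural history — an order of magnitude larger
than the change detectable in clinical scores over the same interval.

The same workflow is available from the shell:

```
musclempi simulate --config cohort.yaml --out data/ --seed 1
musclempi mpi --data data/ --out mpi.csv
musclempi rates --mpi mpi.csv --clinical data/clinical.csv --out rates.csv
musclempi analyze --mpi mpi.csv --clinical data/clinical.csv --out report/
musclempi run-all --config cohort.yaml --out run/ --seed 1   # all of the above
```

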