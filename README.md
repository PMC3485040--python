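# scanqa

Quality-assurance and test-retest reliability metrics for multimodal MRI
(structural T1, resting-state BOLD, diffusion tensor imaging), with synthetic
phantoms that make every metric testable without scanner data.

Longitudinal and multi-site neuroimaging studies must know whether a scanner
swap, a software upgrade or a major hardware repair (for example a gradient
coil replacement) shifts the numbers they care about. `scanqa` implements a
compact battery of per-session metrics and the statistics used to compare
them across scanner conditions:

* **ROI volumes** — per-label volume (cm³) of a segmentation label map,
  after global intensity normalization (each image scaled by
  G = reference / S, with S the mean within-brain intensity).
* **Stretch factor** — a 12-parameter affine registration of the native T1
  to a template (an external standard template or another session of the
  same subject), with the linear part decomposed as L = R·S·K (rotation ×
  positive per-axis scales × unit skew). The per-axis scales sx, sy, sz and
  their product (the determinant, an Atlas-Scaling-Factor analogue) index
  geometric/gradient distortion.
* **Temporal SNR** — for a BOLD series, tSNR = mean(m)/sd(m) of the ROI-mean
  time course m(t), after discarding initial volumes, Gaussian smoothing
  (FWHM mm), high-pass drift removal and nuisance regression (motion, tissue
  means, global signal).
* **FA / MD** — per-voxel diffusion tensors from an ordinary least-squares
  fit of ln S = ln S0 − b·gᵀDg, eigenvalues λ1 ≥ λ2 ≥ λ3, mean diffusivity
  MD = (λ1+λ2+λ3)/3 and fractional anisotropy
  FA = √(3/2) · √Σ(λi−λ̄)² / √Σλi², summarized over ROIs.
* **Motion QC** — maximum adjacent-volume displacement from rigid-motion
  parameter files, and the anterior/superior background-intensity ratio of a
  T1 volume (ghosting detector; a ratio above 1 flags likely motion).
* **Reliability statistics** — one-way ANOVA across conditions, the
  Shrout–Fleiss consistency ICC(3,1) = (BMS − EMS)/(BMS + (k−1)·EMS),
  paired post-hoc t-tests, and reconstruction of a balanced one-way ANOVA
  from published per-condition means and standard errors.

File formats are the standard ones: NIfTI-1 images, FSL-style `bval`/`bvec`
gradient tables, 4×4 text `.mat` affines, and 6-column `.par` motion files.

## Worked example

Simulate a diffusion phantom with a known tensor, fit it, and summarize:

```python
import numpy as np
import scanqa as sq
from scanqa.study import demo_scheme
from scanqa.dti import fa_map, md_map

spec = sq.DwiPhantomSpec(
    shape=(10, 10, 10), voxel_dims=(2, 2, 2),
    regions=[sq.DwiRegionSpec(1, (10, 10, 10), (7, 7, 7),
                              np.diag([1.7e-3, 0.3e-3, 0.2e-3]), "wm")],
    s0=1000.0,
)
scheme = demo_scheme()                       # 2 b=0 + 12 icosahedral directions
dwi = sq.make_dwi_phantom(spec, scheme, seed=0)
labels = sq.dwi_phantom_labels(spec)
field = sq.fit_tensor(dwi, scheme, labels.mask())
fa_mean, fa_sd, n = sq.roi_mean_metric(fa_map(field), labels.mask(1))
md_mean, _, _ = sq.roi_mean_metric(md_map(field), labels.mask(1))
print(f"FA  {fa_mean:.4f} +/- {fa_sd:.4f}  (n={n})")
print(f"MD  {md_mean*1e3:.4f} x 10^-3 mm^2/s")
```

```
FA  0.8359 +/- 0.0000  (n=160)
MD  0.7333 x 10^-3 mm^2/s
```

The noiseless fit reproduces the programmed tensor exactly: FA 0.8359 is the
anisotropy of eigenvalues (1.7, 0.3, 0.2)×10⁻³ mm²/s and MD is their mean —
the scale of healthy white matter.

Reliability across three scanner conditions from a 6-subject metric table
(rows subjects, columns conditions, e.g. thalamus volumes in cm³):

```python
table = np.array([
    [8.01, 8.05, 8.10], [7.40, 7.38, 7.44], [8.90, 8.88, 8.92],
    [8.30, 8.33, 8.31], [7.80, 7.77, 7.82], [8.55, 8.54, 8.58],
])
anova = sq.one_way_anova([table[:, j] for j in range(3)])
icc = sq.icc_consistency(table)
print(f"F_{anova.df_between},{anova.df_within} = {anova.f:.2f}, "
      f"p = {anova.p:.2f}, ICC = {icc.icc:.2f}")
```

```
F_2,15 = 0.01, p = 0.99, ICC = 1.00
```

No condition effect (F ≈ 0) and between-subject variance dominating the
condition error (ICC ≈ 1): the reproducible-hardware signature.

## Command line

```sh
scanqa demo --seed 0 --outdir demo_study      # full synthetic 6x3 study
scanqa t1-volumes --labels labels.nii.gz
scanqa t1-stretch --moving t1.nii.gz --template mni.nii.gz --save-mat out.mat
scanqa t1-qc-ratio --image t1.nii.gz
scanqa bold-tsnr --bold bold.nii.gz --roi dmn.nii.gz --motion bold.par \
    --fwhm 5 --highpass 150 --discard 4
scanqa dti-fit --dwi dwi.nii.gz --bval d.bval --bvec d.bvec \
    --mask mask.nii.gz --out-fa fa.nii.gz --out-md md.nii.gz
scanqa report --table metrics.csv --reference-condition 2
```

## Documentation

`docs/methods.md` describes the models, the synthetic phantoms, the
numerical choices and the known limitations.
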