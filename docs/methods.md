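# Methods

`scanqa` quantifies how reproducible standard neuroimaging measurements are
across scanner conditions (two nominally identical scanners, or the same
scanner before and after a hardware repair). A "study" is a set of sessions
— unique (subject, condition) pairs — from which per-session metrics are
extracted and compared across conditions. This note records the models, the
defaults and why, what the synthetic phantoms do and do not emulate, and the
numerical choices that were genuinely open.

## Structural metrics

**Global intensity normalization.** Receiver gain, coil loading and
positioning shift the global intensity scale between sessions, so each T1
volume is multiplied by G = reference_mean / S, where S is the mean
intensity inside the brain mask. The reference mean defaults to 1000
(dimensionless intensity units; any positive constant works since everything
downstream is either intensity-ratio-based or geometry-based). The
normalized image has within-mask mean equal to the reference by
construction.

**ROI volumes.** volume(label) = voxel count × voxel volume / 1000, in cm³.
Labels are consumed as integer NIfTI maps (segmentation itself — e.g. FSL
FIRST — is upstream of this toolkit). Volumes are exactly invariant under
intensity normalization.

**Stretch factor.** The 12-parameter affine T mapping the native volume to
a template is estimated by minimizing the mean squared difference between
the mean/variance-normalized template and the resampled moving image.
Parameters are 3 translations (mm), 3 Euler rotations, 3 log-scales and 3
skews, composed as L = Rz·Ry·Rx · diag(s) · K about the template centre.
Optimization is deterministic: a 3-level pyramid (subsampling 4, 2, 1 with
matched Gaussian pre-smoothing), Powell direction-set search at each level,
then a Nelder–Mead polish at full resolution with an explicitly sized
initial simplex (scipy's default simplex collapses near a zero start). If no
candidate improves on the identity, the identity transform is returned and
flagged unconverged.

The transform's linear part is factored as L = R·S·K (rotation × positive
diagonal × unit upper-triangular skew) via QR with signs absorbed into the
rotation. The scales (sx, sy, sz) are the per-axis stretch factors; their
product equals det L, which is also reported as the single-number
scaling summary. A negative determinant (a reflection, which no physical
gradient change can produce) is an error naming the flipped axis.

Parameter-recovery behaviour on smooth phantoms: a 5% uniform scale is
recovered within 0.002, a 5 mm translation within 0.1 mm, and
self-registration returns unity scales to at least 4 decimals. Accuracy
depends on image smoothness — see Limitations.

**Background motion ratio.** Motion during a T1 scan leaks ghost energy
into the background along the phase-encoding (anterior) direction, while
the region above the head stays clean. The metric is the ratio of mean
intensity in an anterior background box to a superior background box; a
ratio above 1 flags the session for visual inspection. Box bounds are
closed, 1-based voxel-index intervals; the defaults are 20×10×40 and
20×40×10 boxes (8000 voxels each) placed for a 256³ 1 mm lattice, and are
configurable for other fields of view.

## BOLD temporal SNR

tSNR is computed on the **ROI-mean time course**: m(t) is the average over
all ROI voxels per volume, and tSNR = mean(m)/sd(m) (sample sd, n−1).
Functional-network ROIs share coherent spontaneous fluctuations, and the
aggregated series — not the average of per-voxel tSNRs — is the quantity
that reaches the several-hundred range on a well-behaved 3T system. A
voxelwise mode exists behind a flag for comparison.

The preprocessing chain, applied to motion-corrected input:

1. discard the first 4 volumes (T1 saturation), configurable;
2. spatial Gaussian smoothing, FWHM 5 mm default, sd = FWHM/(2√(2 ln 2))
   per axis scaled by voxel size;
3. high-pass temporal filtering, cutoff 150 s default: per voxel, the
   projection onto a low-frequency **Fourier drift basis** (cosine and sine
   pairs of every harmonic with period ≥ cutoff) is removed. Both phases
   are included deliberately: a cosine-only (DCT) basis passes the
   quadrature component of a drift at an exactly-represented frequency
   untouched (a 300 s sine would survive a 150 s cosine-only filter with
   ~30% of its amplitude). The constant term is kept, so the temporal mean
   is preserved exactly;
4. nuisance regression: ordinary least squares against the 6 motion
   parameters and the mean series of white matter, CSF and the whole brain
   (whichever are supplied), with an intercept; the residual plus the
   voxel's temporal mean is returned so tSNR remains defined. Constant
   regressor columns (e.g. an all-zero motion trace) are dropped.

Slice-time correction and motion correction are out of scope: the toolkit
consumes realigned data plus the exported motion parameters, which isolates
the metrics from realignment engineering. Motion is summarized as the
maximum over adjacent volumes of the Euclidean norm of the translation
difference (mm); rotations are reported separately as a maximum adjacent
angle rather than folded into millimetres, since that would require an
arbitrary head-radius convention.

## Diffusion metrics

The single-tensor model ln S = ln S0 − b·gᵀDg is fit per voxel by ordinary
least squares on log-signals, the classical deterministic approach (WLS
with signal weights is available behind a flag). The design row for a
volume with b-value b and unit direction g = (gx, gy, gz) is
(−b·gx², −b·gy², −b·gz², −2b·gx·gy, −2b·gx·gz, −2b·gy·gz, 1), the unknowns
being (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0). At least 6 unique directions
(up to sign) plus one b=0 volume are required.

Numerics: signals are floored at 10⁻⁶ of the voxel's mean b=0 signal before
the log (noisy magnitudes can reach zero); voxels with no usable b=0 signal
are flagged invalid and excluded from ROI summaries; negative eigenvalues
are clamped to zero with a per-voxel flag and a global count. FA is clipped
to [0, 1] and undefined (all-zero eigenvalues) voxels carry NaN. On a
noiseless phantom the fit reproduces the programmed tensor, ln S0, FA and
MD to ~1e-9 (floating-point round-off through the pseudoinverse), and with
2% Rician noise at 60 directions the ROI-mean FA bias stays below 0.02.

## Reliability statistics

**One-way ANOVA** across conditions uses the standard between/within
decomposition with (k−1, N−k) degrees of freedom. For k conditions of n
subjects each this is F with (k−1, k(n−1)) — e.g. (2, 15) for 3×6. The
degenerate all-identical case reports F = 0, p = 1.

**anova_from_summary** rebuilds the balanced one-way F from per-condition
means and standard errors alone (sd = se·√n; MSW = mean group variance;
MSB = n·Σ(mᵢ−m̄)²/(k−1)), which is exact because the balanced decomposition
depends on the data only through those summaries. It allows published
summary tables to be checked without raw data, and reduces to the squared
two-sample t for k = 2.

**ICC.** The intraclass correlation is the Shrout–Fleiss consistency form

    ICC(3,1) = (BMS − EMS) / (BMS + (k−1)·EMS)

with BMS the between-subject mean square and EMS the residual mean square
of the two-way subject × condition decomposition. This variant treats a
per-condition additive shift as a fixed effect, not error — the right
choice when conditions are the fixed scanner configurations under test —
and estimates σb²/(σb² + σe²) under the additive model. The raw value can
be negative (condition error exceeding subject spread); the reported
headline is clipped to [0, 1] with the raw value retained alongside. An
all-equal table (BMS = EMS = 0) is flagged undefined rather than given a
value. The agreement form ICC(2,1) would penalize pure condition shifts and
give systematically different numbers; it is intentionally not the default.

**Post-hoc comparisons** are paired t-tests of each condition against a
designated reference condition, two-sided, n−1 df, with no multiplicity
correction (none is applied in the comparisons this mirrors).

## Synthetic phantoms

The phantoms exist so that every metric has a knowable ground truth.

* **Structural**: labelled ellipsoids (voxel-centre rasterization rule, so
  region volumes are exact and oracle-checkable) on a noisy air background;
  overlapping ellipsoids are rejected because ground truth must be
  unambiguous. An optional ghost adds intensity to the anterior third of
  the background, emulating a phase-encode motion ghost for the QC-ratio
  metric.
* **BOLD**: each ROI's mean time course is programmed directly as
  baseline + sinusoidal drift + nuisance series + shared Gaussian
  fluctuation of stated sd, plus independent voxel noise that averages
  away in the ROI mean (mirroring coherent network fluctuations). The
  programmed tSNR is baseline/sd; the full pipeline recovers it within a
  few percent at 240 volumes. The emitted motion trace is all-zero — the
  phantom is motion-free by construction.
* **DWI**: per-region SPD tensors generate signals via the closed form
  S = S0·exp(−b·gᵀDg); noiseless mode is exact, Rician mode takes the
  magnitude of two quadrature channels (S+n1, n2), the correct
  magnitude-image noise model.

What they do **not** emulate: anatomy, partial-volume mixtures, bias
fields, susceptibility distortion, physiological noise spectra, k-space
artifacts, or actual subject motion. Passing tests therefore demonstrate
the correctness of the metric computations and their statistical behaviour
under the programmed conditions — not robustness to every artifact of real
data.

A note on texture: structural phantoms used for registration are Gaussian
pre-smoothed. With perfectly sharp synthetic edges, the trilinear
interpolation error at a sub-voxel true transform is as large as the
misalignment signal itself, and sub-0.5% scale changes become unrecoverable
— an artifact of piecewise-constant phantoms, not of real (band-limited)
T1 images.

## The demo study

`demo_phantom_study` builds a full 6-subject × 3-condition study on disk
(structural + BOLD + DWI per session, ~24 s total) and runs it end to end.
Subjects differ in ROI sizes, tensor scale and anisotropy, and network
fluctuation amplitude; conditions differ only in noise realization, except
that condition-3 structural images carry a ~0.6% isocentre scaling
(emulating a gradient miscalibration on a different scanner). The report
then shows the expected signature: nonsignificant ANOVAs and high ICC for
volumes, tSNR and MD, and a clearly detected condition-3 stretch factor
(~0.994) with significant post-hoc t against the condition-2
subject-specific template. Problem sizes (32³ structural, 16×16×8×64 BOLD,
12³ DWI with 14 volumes) are chosen so the full study runs in well under a
minute while keeping every metric in its realistic regime.

## Known limitations

* The registration cost (normalized MSE) assumes same-modality,
  same-contrast image pairs; cross-modality registration would need a
  correlation-ratio or mutual-information cost.
* The optimizer is a deterministic local search: it has no global search
  stage, so large initial misalignments (beyond roughly half the object
  size or ~10° rotation) may not converge; QA use cases start near
  identity by design.
* ICC confidence intervals and mixed-effects variance decompositions are
  out of scope; only the point estimate and its components are reported.
* The high-pass filter is a hard projection (brick-wall in the drift
  basis), not FSL's Gaussian-weighted running-line smoother; for drifts
  well below the cutoff the two agree closely, near the cutoff the
  transition differs.
* NIfTI-2, DICOM and BIDS layouts are not supported; inputs are NIfTI-1
  plus FSL-dialect text files.
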