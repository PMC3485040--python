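"""Synthetic structural, BOLD and DWI phantoms with known ground truth.

Every metric in the toolkit is testable against these: ROI volumes are exact
by construction (ellipsoids rasterized by the voxel-centre rule), the BOLD
phantom's ROI-mean time course has a programmed mean, drift, nuisance
structure and noise level, and the DWI phantom follows the single-tensor
signal equation S = S0 * exp(-b * g'Dg) exactly in noiseless mode.

Design notes
------------
* A voxel belongs to an ellipsoid iff its centre satisfies the ellipsoid
  inequality (<= 1); overlapping ellipsoids are an error because ground-truth
  volumes must be unambiguous.
* BOLD noise is injected at the ROI-mean level (a fluctuation shared by all
  voxels of the ROI, mimicking coherent network fluctuations) plus small
  independent voxel noise that averages away in the ROI mean.
* Rician noise is the magnitude of (S + n1, n2) with n1, n2 ~ N(0, sd), the
  correct magnitude-image noise model; no Gaussian approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import (
    AffineTransform,
    DiffusionScheme,
    Image3D,
    Image4D,
    LabelMap,
    MotionTrace,
)

__all__ = [
    "EllipsoidRegion",
    "StructuralPhantomSpec",
    "BoldRoiSpec",
    "BoldPhantomSpec",
    "DwiRegionSpec",
    "DwiPhantomSpec",
    "make_structural_phantom",
    "make_bold_phantom",
    "bold_nuisance_series",
    "make_dwi_phantom",
    "dwi_phantom_labels",
    "apply_affine_to_image",
    "PhantomSpecError",
]


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is inconsistent."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class EllipsoidRegion:
    """A labelled ellipsoid: centre and semi-axes in mm (world units)."""

    label: int
    center_mm: tuple
    semi_axes_mm: tuple
    intensity: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise PhantomSpecError("region labels must be positive integers")
        if self.intensity < 0:
            raise PhantomSpecError("region intensity must be >= 0")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise PhantomSpecError("ellipsoid semi-axes must be positive")
        if not self.name:
            self.name = f"region_{self.label}"


@dataclass
class StructuralPhantomSpec:
    """T1-like phantom: labelled ellipsoid ROIs on a noisy air background."""

    shape: tuple = (64, 64, 64)
    voxel_dims: tuple = (1.0, 1.0, 1.0)
    regions: list = field(default_factory=list)
    background_intensity: float = 0.0
    background_noise_sd: float = 1.0
    ghost_amplitude: float = 0.0  # added to background in the anterior (high-y) third

    def __post_init__(self) -> None:
        if self.background_intensity < 0:
            raise PhantomSpecError("background intensity must be >= 0")
        extent = np.asarray(self.shape) * np.asarray(self.voxel_dims)
        for r in self.regions:
            c = np.asarray(r.center_mm)
            a = np.asarray(r.semi_axes_mm)
            if np.any(c - a < 0) or np.any(c + a > extent):
                raise PhantomSpecError(
                    f"region {r.label} ellipsoid extends outside the lattice"
                )


@dataclass
class BoldRoiSpec:
    """One BOLD ROI: geometry plus programmed temporal statistics."""

    label: int
    center_mm: tuple
    semi_axes_mm: tuple
    baseline: float
    noise_sd: float  # sd of the shared ROI-mean fluctuation
    name: str = ""

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise PhantomSpecError("ROI noise sd must be > 0")
        if not self.name:
            self.name = f"roi_{self.label}"


@dataclass
class BoldPhantomSpec:
    shape: tuple = (32, 32, 16)
    voxel_dims: tuple = (3.0, 3.0, 3.0)
    tr: float = 2.5
    n_volumes: int = 244
    rois: list = field(default_factory=list)
    drift_amplitude: float = 0.0
    drift_period_s: float = 300.0
    nuisance_amplitudes: tuple = ()  # sinusoid nuisance series, regress-out targets
    voxel_noise_sd: float = 0.5
    background_intensity: float = 0.0  # constant tissue level outside the ROIs

    def __post_init__(self) -> None:
        if self.n_volumes < 8:
            raise PhantomSpecError("BOLD phantom needs n_volumes >= 8")
        if self.drift_period_s <= 0:
            raise PhantomSpecError("drift period must be positive")


@dataclass
class DwiRegionSpec:
    """A DWI phantom region with its ground-truth diffusion tensor (mm^2/s)."""

    label: int
    center_mm: tuple
    semi_axes_mm: tuple
    tensor: np.ndarray  # 3x3 symmetric positive definite
    name: str = ""

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.shape != (3, 3):
            raise PhantomSpecError("tensor must be 3x3")
        if np.max(np.abs(self.tensor - self.tensor.T)) > 1e-12:
            raise PhantomSpecError("tensor must be symmetric")
        if np.min(np.linalg.eigvalsh(self.tensor)) <= 0:
            raise PhantomSpecError("tensor must be positive definite")
        if not self.name:
            self.name = f"region_{self.label}"


@dataclass
class DwiPhantomSpec:
    shape: tuple = (16, 16, 16)
    voxel_dims: tuple = (2.0, 2.0, 2.0)
    regions: list = field(default_factory=list)
    s0: float = 1000.0
    rician_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise PhantomSpecError("S0 must be positive")
        if self.rician_noise_sd < 0:
            raise PhantomSpecError("noise sd must be >= 0")


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------


def _voxel_centers_mm(shape, voxel_dims):
    """World coordinates of voxel centres on a diagonal-affine lattice."""
    axes = [(np.arange(n) + 0.5) * d for n, d in zip(shape, voxel_dims)]
    return np.meshgrid(*axes, indexing="ij")


def _rasterize_regions(shape, voxel_dims, regions) -> np.ndarray:
    """Label lattice from ellipsoid regions; voxel-centre inclusion rule."""
    xs, ys, zs = _voxel_centers_mm(shape, voxel_dims)
    labels = np.zeros(shape, dtype=np.int32)
    for r in regions:
        cx, cy, cz = r.center_mm
        ax, ay, az = r.semi_axes_mm
        inside = ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2 <= 1.0
        if np.any(labels[inside] != 0):
            raise PhantomSpecError(
                f"region {r.label} overlaps a previously placed region"
            )
        labels[inside] = r.label
    return labels


def _diag_affine(voxel_dims) -> np.ndarray:
    aff = np.diag([*voxel_dims, 1.0])
    return aff


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def make_structural_phantom(
    spec: StructuralPhantomSpec, seed: int
) -> tuple[Image3D, LabelMap]:
    """Build a T1-like phantom volume and its ground-truth label map.

    Each labelled region is filled at its nominal intensity; the background
    is ``background_intensity`` plus Gaussian noise of the stated scale.  A
    nonzero ``ghost_amplitude`` raises the background mean in the anterior
    (high-y) third of the lattice, emulating a motion ghost along the
    phase-encoding direction.
    """
    rng = np.random.default_rng(seed)
    labels = _rasterize_regions(spec.shape, spec.voxel_dims, spec.regions)
    voxels = np.full(spec.shape, float(spec.background_intensity))
    voxels += rng.normal(0.0, spec.background_noise_sd, size=spec.shape)
    if spec.ghost_amplitude != 0.0:
        y0 = int(np.ceil(2 * spec.shape[1] / 3))
        voxels[:, y0:, :] += spec.ghost_amplitude
    for r in spec.regions:
        voxels[labels == r.label] = r.intensity
    aff = _diag_affine(spec.voxel_dims)
    names = {r.label: r.name for r in spec.regions}
    return (
        Image3D(voxels, aff, spec.voxel_dims),
        LabelMap(labels, names, affine=aff, voxel_dims=spec.voxel_dims),
    )


def bold_nuisance_series(spec: BoldPhantomSpec) -> np.ndarray:
    """Deterministic nuisance regressor set for a BOLD phantom spec.

    Returns an (n_volumes, k) array of unit-amplitude sinusoids at staggered
    periods; the phantom adds them scaled by ``nuisance_amplitudes``.  The
    same function regenerates the exact series for the regression step.
    """
    t = np.arange(spec.n_volumes) * spec.tr
    cols = []
    for j, _amp in enumerate(spec.nuisance_amplitudes):
        period = 37.0 + 13.0 * j  # co-prime-ish periods, away from the drift period
        cols.append(np.sin(2 * np.pi * t / period + 0.7 * j))
    if not cols:
        return np.empty((spec.n_volumes, 0))
    return np.column_stack(cols)


def make_bold_phantom(
    spec: BoldPhantomSpec, seed: int
) -> tuple[Image4D, LabelMap, MotionTrace]:
    """Build a 4D BOLD phantom, its ROI label map, and an all-zero motion trace.

    The ROI-mean time course of each ROI is (by construction)

        baseline + drift(t) + nuisance(t) + shared_noise(t) + <voxel noise>,

    where shared_noise ~ N(0, roi.noise_sd) is common to every voxel of the
    ROI and the voxel-noise term averages down as 1/sqrt(n_voxels).
    """
    rng = np.random.default_rng(seed)
    labels = _rasterize_regions(spec.shape, spec.voxel_dims, spec.rois)
    t = np.arange(spec.n_volumes) * spec.tr
    drift = spec.drift_amplitude * np.sin(2 * np.pi * t / spec.drift_period_s)
    nuis = bold_nuisance_series(spec)
    nuisance_total = (
        nuis @ np.asarray(spec.nuisance_amplitudes, dtype=float)
        if nuis.size
        else np.zeros(spec.n_volumes)
    )
    voxels = spec.background_intensity + rng.normal(
        0.0, spec.voxel_noise_sd, size=(*spec.shape, spec.n_volumes)
    )
    for roi in spec.rois:
        shared = rng.normal(0.0, roi.noise_sd, size=spec.n_volumes)
        series = roi.baseline + drift + nuisance_total + shared
        voxels[labels == roi.label, :] += series[None, :]
    aff = _diag_affine(spec.voxel_dims)
    names = {r.label: r.name for r in spec.rois}
    img = Image4D(voxels, aff, spec.voxel_dims, spec.tr)
    lmap = LabelMap(labels, names, affine=aff, voxel_dims=spec.voxel_dims)
    trace = MotionTrace(np.zeros((spec.n_volumes, 6)))
    return img, lmap, trace


def dwi_phantom_labels(spec: DwiPhantomSpec) -> LabelMap:
    """Ground-truth label map of a DWI phantom spec (region geometry only)."""
    labels = _rasterize_regions(spec.shape, spec.voxel_dims, spec.regions)
    return LabelMap(
        labels,
        {r.label: r.name for r in spec.regions},
        affine=_diag_affine(spec.voxel_dims),
        voxel_dims=spec.voxel_dims,
    )


def make_dwi_phantom(
    spec: DwiPhantomSpec, scheme: DiffusionScheme, seed: int
) -> Image4D:
    """Simulate DWI signals S = S0 * exp(-b * g'Dg) per region and volume.

    Voxels outside every region are zero (air).  With ``rician_noise_sd`` > 0
    the magnitude of two quadrature channels is taken:
    sqrt((S + n1)^2 + n2^2), n1, n2 ~ N(0, sd).
    """
    rng = np.random.default_rng(seed)
    labels = _rasterize_regions(spec.shape, spec.voxel_dims, spec.regions)
    n = scheme.n_volumes
    voxels = np.zeros((*spec.shape, n))
    for r in spec.regions:
        # b * g'Dg per volume, zero for b=0 rows by construction
        quad = np.einsum("ni,ij,nj->n", scheme.bvecs, r.tensor, scheme.bvecs)
        signal = spec.s0 * np.exp(-scheme.bvals * quad)
        voxels[labels == r.label, :] = signal[None, :]
    if spec.rician_noise_sd > 0:
        sd = spec.rician_noise_sd
        n1 = rng.normal(0.0, sd, size=voxels.shape)
        n2 = rng.normal(0.0, sd, size=voxels.shape)
        voxels = np.sqrt((voxels + n1) ** 2 + n2**2)
    # TR is nominal for DWI; 1 s keeps the 4D container valid
    return Image4D(voxels, _diag_affine(spec.voxel_dims), spec.voxel_dims, tr=1.0)


# ---------------------------------------------------------------------------
# Affine resampling (ground-truth generator for registration tests)
# ---------------------------------------------------------------------------


def apply_affine_to_image(image: Image3D, transform: AffineTransform) -> Image3D:
    """Resample ``image`` on its grid transformed by a world-to-world affine.

    Output voxel x is sampled from the input at world position T * (A x)
    (trilinear); out-of-field voxels are 0.  A transform with scale s > 1
    therefore shrinks the imaged object, so registering the result back to
    the original recovers s as the stretch factor.
    """
    if abs(np.linalg.det(transform.linear)) < 1e-12:
        raise ValueError("singular transform")
    vox2world = image.affine
    # input voxel = A^-1 T A (output voxel)
    m = np.linalg.inv(vox2world) @ transform.matrix @ vox2world
    out = ndimage.affine_transform(
        image.voxels, m[:3, :3], offset=m[:3, 3], order=1, mode="constant", cval=0.0
    )
    return Image3D(out, image.affine, image.voxel_dims)
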