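"""Readers and writers for the on-disk formats the toolkit touches.

NIfTI-1 volumes go through :mod:`nibabel`; gradient tables, rigid-motion
parameter files and 4x4 affine transforms are the plain whitespace text
dialects used by the FSL ecosystem (``.bval``/``.bvec``, ``.par``, ``.mat``).
All images are promoted to floating point on read; label maps stay integer.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger("scanqa.image_io")

__all__ = [
    "Image3D",
    "Image4D",
    "LabelMap",
    "DiffusionScheme",
    "MotionTrace",
    "AffineTransform",
    "ImageFormatError",
    "read_nifti",
    "write_nifti",
    "read_labelmap",
    "write_labelmap",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_affine_mat",
    "write_affine_mat",
    "read_motion_params",
    "write_motion_params",
]


class ImageFormatError(ValueError):
    """Raised when an on-disk file violates the expected format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Image3D:
    """A 3D scalar volume with its voxel-to-world affine (mm)."""

    voxels: np.ndarray
    affine: np.ndarray
    voxel_dims: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_dims = np.asarray(self.voxel_dims, dtype=float)
        if self.voxels.ndim != 3:
            raise ImageFormatError(f"Image3D needs a 3D lattice, got {self.voxels.ndim}D")
        if self.affine.shape != (4, 4):
            raise ImageFormatError("affine must be 4x4")
        if np.any(self.voxel_dims <= 0):
            raise ImageFormatError(f"voxel dimensions must be positive, got {self.voxel_dims}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ImageFormatError("affine linear part is singular")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape


@dataclass
class Image4D:
    """A 4D (x, y, z, t) series with repetition time ``tr`` in seconds."""

    voxels: np.ndarray
    affine: np.ndarray
    voxel_dims: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_dims = np.asarray(self.voxel_dims, dtype=float)
        if self.voxels.ndim != 4:
            raise ImageFormatError(f"Image4D needs a 4D lattice, got {self.voxels.ndim}D")
        if self.voxels.shape[3] < 2:
            raise ImageFormatError("time dimension must be >= 2")
        if not self.tr > 0:
            raise ImageFormatError(f"tr must be positive, got {self.tr}")
        if np.any(self.voxel_dims <= 0):
            raise ImageFormatError(f"voxel dimensions must be positive, got {self.voxel_dims}")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def n_volumes(self) -> int:
        return self.voxels.shape[3]

    def volume(self, t: int) -> Image3D:
        """Extract time point ``t`` as an Image3D."""
        return Image3D(self.voxels[..., t], self.affine, self.voxel_dims)

    def mean_volume(self) -> Image3D:
        return Image3D(self.voxels.mean(axis=3), self.affine, self.voxel_dims)


@dataclass
class LabelMap:
    """Integer-labelled ROI volume; 0 is reserved for background."""

    labels: np.ndarray
    names: dict = field(default_factory=dict)
    affine: np.ndarray | None = None
    voxel_dims: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ImageFormatError("label lattice must be integer-typed")
        if self.labels.ndim != 3:
            raise ImageFormatError("label lattice must be 3D")
        present = set(int(v) for v in np.unique(self.labels)) - {0}
        if self.names:
            missing = present - set(self.names)
            if missing:
                raise ImageFormatError(f"labels without names: {sorted(missing)}")
        else:
            self.names = {lab: f"label_{lab}" for lab in sorted(present)}
        if self.voxel_dims is None:
            self.voxel_dims = np.ones(3)
        self.voxel_dims = np.asarray(self.voxel_dims, dtype=float)
        if self.affine is None:
            self.affine = np.diag([*self.voxel_dims, 1.0])

    def mask(self, label: int | None = None) -> np.ndarray:
        """Boolean mask of one label, or of all nonzero labels."""
        if label is None:
            return self.labels != 0
        return self.labels == label


@dataclass
class DiffusionScheme:
    """Per-volume diffusion weighting: b-value (s/mm^2) and unit direction."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ImageFormatError(
                f"bvecs shape {self.bvecs.shape} does not match {self.bvals.size} b-values"
            )
        if not np.any(self.bvals == 0):
            raise ImageFormatError("scheme needs at least one b=0 entry")
        weighted = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[weighted], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ImageFormatError("non-unit gradient direction for b > 0 (tolerance 1e-3)")
        self.bvecs = self.bvecs.copy()
        self.bvecs[~weighted] = 0.0

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


@dataclass
class MotionTrace:
    """Per-volume rigid-motion parameters: 3 rotations (rad) + 3 translations (mm)."""

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.atleast_2d(np.asarray(self.params, dtype=float))
        if self.params.shape[1] != 6:
            raise ImageFormatError(f"motion trace needs 6 columns, got {self.params.shape[1]}")
        if not np.all(np.isfinite(self.params)):
            raise ImageFormatError("motion trace contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class AffineTransform:
    """4x4 homogeneous world-mm to world-mm transform."""

    matrix: np.ndarray
    source: str = ""
    target: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ImageFormatError("affine transform must be 4x4")
        if np.max(np.abs(self.matrix[3] - np.array([0, 0, 0, 1]))) > 1e-6:
            raise ImageFormatError("bottom row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ImageFormatError("linear part is singular")

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]


# ---------------------------------------------------------------------------
# NIfTI images
# ---------------------------------------------------------------------------


def _load_nifti1(path: str) -> nib.Nifti1Image:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(path)
    except Exception as exc:  # nibabel raises several unrelated types here
        raise ImageFormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    if isinstance(img, nib.Nifti2Image):
        raise ImageFormatError(f"NIfTI-2 is not supported: {path}")
    if not isinstance(img, nib.Nifti1Image):
        raise ImageFormatError(f"expected a NIfTI-1 payload, got {type(img).__name__}: {path}")
    return img


def read_nifti(path: str) -> Image3D | Image4D:
    """Read a NIfTI-1 volume; intensity scaling (scl_slope/scl_inter) is applied.

    3D files come back as :class:`Image3D`, 4D files as :class:`Image4D` with
    ``tr`` taken from the header's fourth pixdim (seconds, FSL convention).
    """
    img = _load_nifti1(path)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    zooms = img.header.get_zooms()
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if any(z <= 0 for z in zooms[:3]):
        raise ImageFormatError(f"zero or negative voxel dimension in header: {zooms[:3]}")
    voxel_dims = np.asarray(zooms[:3], dtype=float)
    if data.ndim == 3:
        return Image3D(data, img.affine, voxel_dims)
    if data.ndim == 4:
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            raise ImageFormatError(f"4D file with nonpositive TR in pixdim[4]: {tr}")
        return Image4D(data, img.affine, voxel_dims, tr)
    raise ImageFormatError(f"unsupported dimensionality {data.ndim} in {path}")


def write_nifti(image: Image3D | Image4D, path: str) -> None:
    """Write an image as float32 NIfTI-1 (re-readable to storage precision)."""
    data = np.asarray(image.voxels, dtype=np.float32)
    out = nib.Nifti1Image(data, image.affine)
    zooms = list(image.voxel_dims)
    if isinstance(image, Image4D):
        zooms.append(image.tr)
        out.header.set_xyzt_units("mm", "sec")
    else:
        out.header.set_xyzt_units("mm")
    out.header.set_zooms(zooms)
    nib.save(out, path)


def read_labelmap(path: str, names: dict | None = None) -> LabelMap:
    """Read an integer NIfTI label volume (no intensity scaling applied)."""
    img = _load_nifti1(path)
    data = np.asarray(img.dataobj.get_unscaled()).astype(np.int32)
    return LabelMap(data, names or {}, affine=img.affine,
                    voxel_dims=np.asarray(img.header.get_zooms()[:3], dtype=float))


def write_labelmap(labelmap: LabelMap, path: str) -> None:
    out = nib.Nifti1Image(labelmap.labels.astype(np.int32), labelmap.affine)
    out.header.set_zooms(list(labelmap.voxel_dims))
    nib.save(out, path)


# ---------------------------------------------------------------------------
# Gradient tables
# ---------------------------------------------------------------------------


def read_bvals_bvecs(bval_path: str, bvec_path: str) -> DiffusionScheme:
    """Parse FSL-style bval/bvec text files into a :class:`DiffusionScheme`.

    The bvec table may be 3 rows x N volumes (FSL dialect) or N x 3; the
    layout is auto-detected from the shape.  An ambiguous 3x3 table is read
    as rows-of-components (the FSL convention) and logged.
    """
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape == (3, 3):
        logger.info("ambiguous 3x3 bvec table in %s: assuming rows are components", bvec_path)
    elif bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        pass  # rows are components already
    elif bvecs.shape[1] == 3:
        bvecs = bvecs.T
    elif bvecs.shape[0] != 3:
        raise ImageFormatError(f"bvec table must be 3xN or Nx3, got {bvecs.shape}")
    bvecs = bvecs.T  # -> (n, 3)
    if bvecs.shape[0] != bvals.size:
        raise ImageFormatError(
            f"bval count {bvals.size} does not match bvec count {bvecs.shape[0]}"
        )
    return DiffusionScheme(bvals, bvecs)


def write_bvals_bvecs(scheme: DiffusionScheme, bval_path: str, bvec_path: str) -> None:
    """Write FSL dialect: one row of b-values; bvecs as 3 rows x N volumes."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.9g")


# ---------------------------------------------------------------------------
# Affine .mat and motion .par text files
# ---------------------------------------------------------------------------


def read_affine_mat(path: str, source: str = "", target: str = "") -> AffineTransform:
    """Read an FSL-style 4-line x 4-number text affine."""
    mat = np.atleast_2d(np.loadtxt(path, dtype=float))
    if mat.shape != (4, 4):
        raise ImageFormatError(f"affine .mat must be 4x4, got {mat.shape}")
    return AffineTransform(mat, source=source, target=target)


def write_affine_mat(transform: AffineTransform, path: str) -> None:
    np.savetxt(path, transform.matrix, fmt="%.12g")


def read_motion_params(path: str) -> MotionTrace:
    """Read an FSL ``.par``-style file: 6 columns per volume (3 rot rad, 3 trans mm)."""
    table = np.atleast_2d(np.loadtxt(path, dtype=float))
    if table.shape[1] != 6:
        raise ImageFormatError(f"motion file must have 6 columns, got {table.shape[1]}")
    return MotionTrace(table)


def write_motion_params(trace: MotionTrace, path: str) -> None:
    np.savetxt(path, trace.params, fmt="%.12g")
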