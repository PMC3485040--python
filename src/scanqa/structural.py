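"""Structural (T1) metrics: intensity normalization, ROI volumes, stretch
factor via 12-parameter affine registration, and the background-intensity
motion check.

The stretch factor quantifies the linear scaling needed to register a brain
to a template (an Atlas-Scaling-Factor analogue): the affine's linear part
is factored as L = R * S * K with R a rotation, S = diag(sx, sy, sz) the
per-axis stretch, and K a unit upper-triangular skew.  Both the per-axis
scales and the determinant (their product) are reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .image_io import AffineTransform, Image3D, LabelMap

logger = logging.getLogger("scanqa.structural")

__all__ = [
    "NormalizationResult",
    "ScaleDecomposition",
    "QcRoiBounds",
    "RegistrationOptions",
    "global_intensity_normalize",
    "roi_volumes",
    "register_affine",
    "decompose_scales",
    "background_motion_ratio",
    "DEFAULT_QC_BOUNDS",
]


# ---------------------------------------------------------------------------
# Global intensity normalization
# ---------------------------------------------------------------------------


@dataclass
class NormalizationResult:
    """Scaling applied by global intensity normalization: G = reference / S."""

    scale: float
    input_mean: float
    reference_mean: float


def global_intensity_normalize(
    image: Image3D, brain_mask: np.ndarray, reference_mean: float = 1000.0
) -> tuple[Image3D, NormalizationResult]:
    """Rescale an image so its within-mask mean equals ``reference_mean``.

    The image is multiplied by G = reference_mean / S where S is the mean
    intensity inside the brain mask; session-to-session receiver-gain and
    coil-loading differences cancel out of downstream intensity comparisons.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != image.voxels.shape:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        raise ValueError("empty brain mask")
    s = float(image.voxels[mask].mean())
    if s <= 0:
        raise ValueError(f"nonpositive within-mask mean intensity: {s}")
    g = reference_mean / s
    out = Image3D(image.voxels * g, image.affine, image.voxel_dims)
    return out, NormalizationResult(scale=g, input_mean=s, reference_mean=reference_mean)


# ---------------------------------------------------------------------------
# ROI volumes
# ---------------------------------------------------------------------------


def roi_volumes(labelmap: LabelMap, voxel_dims=None) -> dict:
    """Per-label volumes in cm^3: voxel count x voxel volume (mm^3) / 1000.

    Labels listed in the name table but absent from the lattice get volume
    0.0 with a warning (a vanished structure is a finding, not a crash).
    """
    vd = np.asarray(voxel_dims if voxel_dims is not None else labelmap.voxel_dims, dtype=float)
    if np.any(vd <= 0):
        raise ValueError("voxel dimensions must be positive")
    voxel_cm3 = float(np.prod(vd)) / 1000.0
    labs, counts = np.unique(labelmap.labels, return_counts=True)
    count_of = dict(zip(labs.tolist(), counts.tolist()))
    out = {}
    for label in sorted(labelmap.names):
        n = count_of.get(label, 0)
        if n == 0:
            warnings.warn(f"label {label} ({labelmap.names[label]}) absent; volume 0")
        out[label] = n * voxel_cm3
    return out


# ---------------------------------------------------------------------------
# 12-parameter affine registration
# ---------------------------------------------------------------------------


@dataclass
class RegistrationOptions:
    """Deterministic multi-resolution affine registration settings.

    Cost is the mean squared difference between the mean/variance-normalized
    template and resampled moving image.  Optimization is Powell direction-set
    search (sequential line minimizations) at pyramid levels with subsampling
    factors ``pyramid``, followed by a Nelder-Mead polish at full resolution.
    Everything is seed-free and deterministic.
    """

    pyramid: tuple = (4, 2, 1)
    powell_maxiter: int = 8
    polish_maxiter: int = 300
    # parameter scaling: translations mm, rotations rad, log-scales, skews
    param_scales: tuple = (1.0, 1.0, 1.0, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02, 0.02)
    xtol: float = 1e-6
    ftol: float = 1e-12


def _params_to_matrix(p: np.ndarray, center: np.ndarray) -> np.ndarray:
    """12 parameters -> 4x4 world affine, rotation about ``center``.

    Layout: p = (tx, ty, tz, rx, ry, rz, log sx, log sy, log sz, kxy, kxz, kyz);
    linear part L = Rz Ry Rx * diag(s) * K with K unit upper triangular.
    """
    t = p[:3]
    rx, ry, rz = p[3:6]
    s = np.exp(p[6:9])
    kxy, kxz, kyz = p[9:12]
    cx, sx_ = np.cos(rx), np.sin(rx)
    cy, sy_ = np.cos(ry), np.sin(ry)
    cz, sz_ = np.cos(rz), np.sin(rz)
    rmx = np.array([[1, 0, 0], [0, cx, -sx_], [0, sx_, cx]])
    rmy = np.array([[cy, 0, sy_], [0, 1, 0], [-sy_, 0, cy]])
    rmz = np.array([[cz, -sz_, 0], [sz_, cz, 0], [0, 0, 1]])
    k = np.array([[1, kxy, kxz], [0, 1, kyz], [0, 0, 1]])
    lin = rmz @ rmy @ rmx @ np.diag(s) @ k
    mat = np.eye(4)
    mat[:3, :3] = lin
    mat[:3, 3] = t + center - lin @ center
    return mat


def _znorm(a: np.ndarray) -> np.ndarray:
    sd = a.std()
    if sd == 0:
        return np.zeros_like(a)
    return (a - a.mean()) / sd


def _subsample(vol: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol, sigma=factor / 2.0)
    return sm[::factor, ::factor, ::factor]


def register_affine(
    moving: Image3D, template: Image3D, options: RegistrationOptions | None = None
) -> AffineTransform:
    """Estimate the 12-parameter affine mapping moving-world to template-world.

    Returns an :class:`AffineTransform` whose ``meta`` records convergence
    (``converged``), the initial and final normalized-MSE cost, and the raw
    parameter vector.  If no parameter set improves on the identity, the
    identity is returned with ``converged`` False.
    """
    opts = options or RegistrationOptions()
    t_shape = np.asarray(template.voxels.shape)
    center = template.affine @ np.array([*((t_shape - 1) / 2.0), 1.0])
    center = center[:3]
    inv_mov_aff = np.linalg.inv(moving.affine)
    scales = np.asarray(opts.param_scales)

    def cost_for_level(t_level: np.ndarray, a_t_level: np.ndarray, mov_vol: np.ndarray):
        t_norm = _znorm(t_level)
        n = t_level.size

        def cost(x: np.ndarray) -> float:
            p = x * scales
            mat = _params_to_matrix(p, center)
            m = inv_mov_aff @ np.linalg.inv(mat) @ a_t_level
            res = ndimage.affine_transform(
                mov_vol, m[:3, :3], offset=m[:3, 3], order=1,
                mode="constant", cval=0.0, output_shape=t_level.shape,
            )
            return float(np.sum((t_norm - _znorm(res)) ** 2) / n)

        return cost

    x = np.zeros(12)
    for factor in opts.pyramid:
        t_level = _subsample(template.voxels, factor)
        a_t_level = template.affine @ np.diag([factor, factor, factor, 1.0])
        mov_vol = (
            ndimage.gaussian_filter(moving.voxels, sigma=factor / 2.0)
            if factor > 1
            else moving.voxels
        )
        cost = cost_for_level(t_level, a_t_level, mov_vol)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                cost, x, method="Powell",
                options={"maxiter": opts.powell_maxiter, "xtol": opts.xtol,
                         "ftol": opts.ftol},
            )
        x = res.x
        logger.debug("pyramid level %d: cost %.3e", factor, res.fun)

    # full-resolution cost for the identity-improvement check and the polish
    cost_full = cost_for_level(
        template.voxels, template.affine.copy(), moving.voxels
    )
    cost0 = cost_full(np.zeros(12))
    # explicit initial simplex: scipy's default collapses near x = 0
    simplex = np.vstack([x, x + 0.05 * np.eye(12)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            cost_full, x, method="Nelder-Mead",
            options={"maxiter": opts.polish_maxiter, "xatol": 1e-7,
                     "fatol": 1e-14, "initial_simplex": simplex},
        )
    final_cost = float(res.fun)
    p = res.x * scales
    if final_cost > cost0 + 1e-12:
        logger.warning("registration failed to improve on identity; returning identity")
        return AffineTransform(
            np.eye(4), meta={"converged": False, "cost_initial": cost0,
                             "cost_final": cost0, "params": np.zeros(12)}
        )
    converged = final_cost < cost0 - 1e-12 or cost0 <= 1e-10
    return AffineTransform(
        _params_to_matrix(p, center),
        meta={"converged": bool(converged), "cost_initial": cost0,
              "cost_final": final_cost, "params": p},
    )


# ---------------------------------------------------------------------------
# Scale decomposition (avscale-style)
# ---------------------------------------------------------------------------


@dataclass
class ScaleDecomposition:
    """L = R * S * K factorization of an affine's linear part."""

    scales: np.ndarray  # (sx, sy, sz), positive
    skews: np.ndarray  # (kxy, kxz, kyz) of the unit upper-triangular K
    rotation: np.ndarray  # 3x3 rotation R
    determinant: float


def decompose_scales(transform: AffineTransform) -> ScaleDecomposition:
    """Factor the linear part as rotation x positive diagonal x unit skew.

    Implemented as a QR decomposition with the diagonal signs absorbed into
    Q, i.e. the Gram-Schmidt construction FSL's avscale uses.  A negative
    determinant means a reflection, which a physical scanner-geometry change
    cannot produce; the flipped axis is named in the error.
    """
    lin = transform.linear
    det = float(np.linalg.det(lin))
    if det <= 0:
        q, r = np.linalg.qr(lin)
        diag = np.diag(r)
        axis = "xyz"[int(np.argmin(diag))]
        raise ValueError(
            f"negative determinant ({det:.6g}): reflection along axis {axis}"
        )
    q, r = np.linalg.qr(lin)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    q = q * signs[None, :]
    r = r * signs[:, None]
    s = np.diag(r).copy()
    k = r / s[:, None]
    return ScaleDecomposition(
        scales=s,
        skews=np.array([k[0, 1], k[0, 2], k[1, 2]]),
        rotation=q,
        determinant=det,
    )


# ---------------------------------------------------------------------------
# Background-intensity motion QC
# ---------------------------------------------------------------------------


@dataclass
class QcRoiBounds:
    """Closed 1-based voxel-index intervals for the two background QC boxes.

    ``anterior`` sits in front of the head along the phase-encoding axis
    (motion ghosts land there); ``superior`` sits above the head and serves
    as the reference.  Each is ((xlo, xhi), (ylo, yhi), (zlo, zhi)).
    """

    anterior: tuple
    superior: tuple

    def __post_init__(self) -> None:
        for region in (self.anterior, self.superior):
            for lo, hi in region:
                if hi < lo:
                    raise ValueError(f"interval [{lo}, {hi}] is empty")
                if lo < 1:
                    raise ValueError("bounds are 1-based; lo must be >= 1")

    @staticmethod
    def _count(region) -> int:
        return int(np.prod([hi - lo + 1 for lo, hi in region]))

    @property
    def anterior_n_voxels(self) -> int:
        return self._count(self.anterior)

    @property
    def superior_n_voxels(self) -> int:
        return self._count(self.superior)


#: The published QC box coordinates: 20 x 10 x 40 and 20 x 40 x 10 voxels,
#: 8000 voxels each, on a 256-cube 1 mm lattice.
DEFAULT_QC_BOUNDS = QcRoiBounds(
    anterior=((90, 109), (246, 255), (186, 225)),
    superior=((65, 84), (156, 195), (246, 255)),
)


@dataclass
class MotionRatioResult:
    ratio: float
    flagged: bool
    anterior_mean: float
    superior_mean: float


def _extract_box(voxels: np.ndarray, region) -> np.ndarray:
    slices = []
    for ax, (lo, hi) in enumerate(region):
        if hi > voxels.shape[ax]:
            raise ValueError(
                f"QC region axis {ax} interval [{lo}, {hi}] exceeds lattice "
                f"size {voxels.shape[ax]}"
            )
        slices.append(slice(lo - 1, hi))  # closed 1-based -> half-open 0-based
    return voxels[tuple(slices)]


def background_motion_ratio(
    image: Image3D, bounds: QcRoiBounds = DEFAULT_QC_BOUNDS
) -> MotionRatioResult:
    """Anterior/superior background intensity ratio; > 1 flags likely motion.

    Motion during a T1 scan smears ghost energy into the background anterior
    to the head (the phase-encoding direction), while the region above the
    head stays clean; their mean-intensity ratio is a cheap ghost detector.
    """
    ant = _extract_box(image.voxels, bounds.anterior)
    sup = _extract_box(image.voxels, bounds.superior)
    sup_mean = float(sup.mean())
    if sup_mean == 0:
        raise ValueError("superior reference region has zero mean intensity")
    ant_mean = float(ant.mean())
    ratio = ant_mean / sup_mean
    return MotionRatioResult(
        ratio=ratio, flagged=bool(ratio > 1.0),
        anterior_mean=ant_mean, superior_mean=sup_mean,
    )
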