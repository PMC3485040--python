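"""Diffusion-tensor metrics: log-linear tensor fit, eigenvalues, FA and MD.

The single-tensor model is ln S = ln S0 - b g'Dg.  With the design row
(-b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz, 1) the unknowns
(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0) are estimated per voxel by ordinary
least squares on the log-signals (the classic FDT default; weighted fits are
available behind a flag).  Eigenvalues l1 >= l2 >= l3 of the symmetric D
give

    MD = (l1 + l2 + l3) / 3
    FA = sqrt(3/2) * sqrt(sum (li - lbar)^2) / sqrt(sum li^2)

with FA in [0, 1]: 0 for isotropic diffusion, 1 for purely one-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import DiffusionScheme, Image3D, Image4D

__all__ = [
    "TensorField",
    "ScalarMap",
    "build_design_matrix",
    "fit_tensor",
    "fa",
    "md",
    "roi_mean_metric",
]


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors and their eigen-decomposition.

    ``tensors`` stores the 6 unique entries (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    in mm^2/s; ``eigenvalues`` are sorted descending.  Voxels whose raw fit
    produced a negative eigenvalue are clamped to zero and flagged in
    ``clamped``; voxels with unusable signal are flagged in ``invalid``.
    """

    tensors: np.ndarray  # (..., 6)
    log_s0: np.ndarray  # (...,)
    eigenvalues: np.ndarray  # (..., 3) descending
    mask: np.ndarray  # analysis mask
    clamped: np.ndarray  # bool, negative eigenvalue clamped
    invalid: np.ndarray  # bool, degenerate signal, excluded from summaries

    @property
    def n_clamped(self) -> int:
        return int(self.clamped.sum())

    def tensor_matrix(self, index) -> np.ndarray:
        """Full 3x3 symmetric tensor at one voxel index."""
        dxx, dyy, dzz, dxy, dxz, dyz = self.tensors[index]
        return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


@dataclass
class ScalarMap:
    """FA (dimensionless) or MD (mm^2/s) lattice with its validity mask."""

    values: np.ndarray
    mask: np.ndarray
    name: str = ""

    def to_image(self, affine, voxel_dims) -> Image3D:
        out = np.where(self.mask, self.values, 0.0)
        return Image3D(out, affine, voxel_dims)


def build_design_matrix(scheme: DiffusionScheme) -> np.ndarray:
    """One row per volume mapping (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0) to ln S."""
    b = scheme.bvals
    g = scheme.bvecs
    weighted = g[b > 0]
    if weighted.shape[0] >= 1:
        # directions are sign-invariant: canonicalize so the first nonzero
        # component is positive before counting unique ones
        canon = weighted.copy()
        for row in canon:
            nz = np.flatnonzero(np.abs(row) > 1e-12)
            if nz.size and row[nz[0]] < 0:
                row *= -1
        uniq = np.unique(np.round(canon, 6), axis=0)
        if uniq.shape[0] < 6:
            raise ValueError(
                f"need >= 6 unique nonzero gradient directions, got {uniq.shape[0]}"
            )
    else:
        raise ValueError("scheme has no diffusion-weighted volumes")
    x = np.column_stack([
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
        np.ones_like(b),
    ])
    if np.linalg.matrix_rank(x) < 7:
        raise ValueError("rank-deficient DTI design (directions not independent)")
    return x


def fit_tensor(
    dwi: Image4D,
    scheme: DiffusionScheme,
    mask: np.ndarray,
    weighted: bool = False,
) -> TensorField:
    """Ordinary least squares on log-signals, per voxel inside the mask.

    Signals are floored at 1e-6 of the voxel's estimated S0 before the log
    (nonpositive magnitudes cannot occur in theory but do in noisy data).
    ``weighted=True`` switches to WLS with the squared signals as weights.
    Voxels whose b=0 signal is entirely zero are flagged invalid and carry
    zero tensors.
    """
    if dwi.n_volumes != scheme.n_volumes:
        raise ValueError(
            f"DWI has {dwi.n_volumes} volumes but scheme has {scheme.n_volumes}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.voxels.shape[:3]:
        raise ValueError("mask shape does not match DWI grid")
    if not mask.any():
        raise ValueError("empty analysis mask")
    x = build_design_matrix(scheme)
    sig = dwi.voxels[mask, :]  # (v, n)
    s0_est = sig[:, scheme.b0_mask].mean(axis=1)
    invalid_vox = s0_est <= 0
    floor = np.where(invalid_vox, 1.0, 1e-6 * np.abs(s0_est))
    logs = np.log(np.maximum(sig, floor[:, None]))
    if weighted:
        beta = np.empty((sig.shape[0], 7))
        w = np.maximum(sig, floor[:, None])  # weight ~ signal (sd of ln S ~ 1/S)
        for i in range(sig.shape[0]):
            xw = x * w[i][:, None]
            beta[i] = np.linalg.lstsq(xw, logs[i] * w[i], rcond=None)[0]
    else:
        beta = np.linalg.lstsq(x, logs.T, rcond=None)[0].T  # (v, 7)
    dxx, dyy, dzz, dxy, dxz, dyz = (beta[:, i] for i in range(6))
    dmats = np.empty((sig.shape[0], 3, 3))
    dmats[:, 0, 0], dmats[:, 1, 1], dmats[:, 2, 2] = dxx, dyy, dzz
    dmats[:, 0, 1] = dmats[:, 1, 0] = dxy
    dmats[:, 0, 2] = dmats[:, 2, 0] = dxz
    dmats[:, 1, 2] = dmats[:, 2, 1] = dyz
    evals = np.linalg.eigvalsh(dmats)[:, ::-1]  # descending
    clamped_vox = evals[:, -1] < 0
    evals = np.maximum(evals, 0.0)

    shape = dwi.voxels.shape[:3]
    tensors = np.zeros((*shape, 6))
    log_s0 = np.zeros(shape)
    eigenvalues = np.zeros((*shape, 3))
    clamped = np.zeros(shape, dtype=bool)
    invalid = np.zeros(shape, dtype=bool)
    tensors[mask] = beta[:, :6]
    log_s0[mask] = beta[:, 6]
    eigenvalues[mask] = evals
    clamped[mask] = clamped_vox
    inv = np.zeros(shape, dtype=bool)
    inv[mask] = invalid_vox
    invalid |= inv
    return TensorField(tensors, log_s0, eigenvalues, mask, clamped, invalid)


def fa(l1, l2, l3):
    """Fractional anisotropy of an eigenvalue triple (scalar or arrays).

    All-zero triples are undefined and come back as NaN."""
    l1, l2, l3 = np.broadcast_arrays(
        np.asarray(l1, dtype=float), np.asarray(l2, dtype=float), np.asarray(l3, dtype=float)
    )
    lam = np.stack([l1, l2, l3], axis=-1)
    denom2 = np.sum(lam**2, axis=-1)
    mean = lam.mean(axis=-1, keepdims=True)
    num2 = np.sum((lam - mean) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(1.5) * np.sqrt(num2) / np.sqrt(denom2)
    out = np.where(denom2 == 0, np.nan, out)
    out = np.clip(out, 0.0, 1.0)  # NaN propagates through clip

    if out.ndim == 0:
        return float(out)
    return out


def md(l1, l2, l3):
    """Mean diffusivity: the average of the three eigenvalues (mm^2/s)."""
    l1 = np.asarray(l1, dtype=float)
    out = (l1 + np.asarray(l2, dtype=float) + np.asarray(l3, dtype=float)) / 3.0
    if out.ndim == 0:
        return float(out)
    return out


def fa_map(field: TensorField) -> ScalarMap:
    ev = field.eigenvalues
    values = fa(ev[..., 0], ev[..., 1], ev[..., 2])
    mask = field.mask & ~field.invalid & ~np.isnan(values)
    return ScalarMap(np.nan_to_num(values), mask, name="FA")


def md_map(field: TensorField) -> ScalarMap:
    ev = field.eigenvalues
    values = md(ev[..., 0], ev[..., 1], ev[..., 2])
    return ScalarMap(values, field.mask & ~field.invalid, name="MD")


def roi_mean_metric(scalar_map: ScalarMap, roi_mask: np.ndarray) -> tuple[float, float, int]:
    """Mean, sample sd and count of a scalar map over an ROI.

    Only voxels inside both the ROI and the map's validity mask count; a
    single-voxel ROI gets sd 0 (undefined sample sd flagged as zero)."""
    roi = np.asarray(roi_mask, dtype=bool)
    sel = roi & scalar_map.mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError("ROI does not intersect the analysis mask")
    vals = scalar_map.values[sel]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return float(vals.mean()), sd, n


__all__ += ["fa_map", "md_map"]
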