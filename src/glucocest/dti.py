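"""Diffusion-tensor fitting from an S0 + 6-direction DWI acquisition.

With exactly six non-collinear gradient directions the log-linearized tensor
model

    ln(S_i / S0) = -b * g_i^T D g_i

is a square linear system per voxel: the six unique tensor elements are the
exact solution when the data are noiseless.  Mean diffusivity (ADC) is
trace(D)/3; fractional anisotropy is computed from the eigenvalues after
clamping negatives (a noise artifact) to zero:

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiffusionSet", "TensorMap", "fit_tensor", "roi_summary", "DEFAULT_BVECS"]

#: Dual-gradient six-direction scheme (rows are unit vectors).
DEFAULT_BVECS = np.array(
    [
        [1, 1, 0],
        [1, -1, 0],
        [1, 0, 1],
        [1, 0, -1],
        [0, 1, 1],
        [0, 1, -1],
    ],
    dtype=float,
) / np.sqrt(2.0)


@dataclass
class DiffusionSet:
    """S0 image plus six diffusion-weighted images and their encoding."""

    s0_image: np.ndarray
    dwi_images: np.ndarray      # (..., 6)
    bvecs: np.ndarray           # (6, 3) unit vectors
    bval: float                 # s/mm^2

    def __post_init__(self) -> None:
        self.s0_image = np.asarray(self.s0_image, dtype=float)
        self.dwi_images = np.asarray(self.dwi_images, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (6, 3):
            raise ValueError("bvecs must have shape (6, 3)")
        norms = np.linalg.norm(self.bvecs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("bvecs must be unit vectors")
        if self.bval <= 0:
            raise ValueError("bval must be positive")
        if self.dwi_images.shape != self.s0_image.shape + (6,):
            raise ValueError("dwi_images must be s0 shape + (6,)")
        if np.linalg.matrix_rank(design_matrix(self.bvecs)) < 6:
            raise ValueError("bvec set is rank-deficient; directions do not span")


@dataclass
class TensorMap:
    """Per-voxel diffusion tensor with derived ADC and FA maps."""

    tensor: np.ndarray   # (..., 6): Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    adc: np.ndarray
    fa: np.ndarray
    mask: np.ndarray


def design_matrix(bvecs: np.ndarray) -> np.ndarray:
    """Rows [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz] per direction."""
    g = np.asarray(bvecs, dtype=float)
    return np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def tensor_from_elements(d6: np.ndarray) -> np.ndarray:
    """Expand (..., 6) unique elements to (..., 3, 3) symmetric tensors."""
    d6 = np.asarray(d6, dtype=float)
    out = np.empty(d6.shape[:-1] + (3, 3))
    out[..., 0, 0] = d6[..., 0]
    out[..., 1, 1] = d6[..., 1]
    out[..., 2, 2] = d6[..., 2]
    out[..., 0, 1] = out[..., 1, 0] = d6[..., 3]
    out[..., 0, 2] = out[..., 2, 0] = d6[..., 4]
    out[..., 1, 2] = out[..., 2, 1] = d6[..., 5]
    return out


def fit_tensor(ds: DiffusionSet, mask: np.ndarray | None = None) -> TensorMap:
    """Exact log-linear tensor fit per voxel.

    Voxels with non-positive S0 or DWI signal, or with any S_i >= S0 (a
    non-attenuating direction, excluded from the log-linear model), are
    masked out rather than fitted.
    """
    spatial = ds.s0_image.shape
    s0 = ds.s0_image.reshape(-1)
    S = ds.dwi_images.reshape(-1, 6)
    good = (s0 > 0) & np.all(S > 0, axis=1) & np.all(S < s0[:, None], axis=1)
    good &= np.isfinite(s0) & np.all(np.isfinite(S), axis=1)
    if mask is not None:
        good &= np.asarray(mask, dtype=bool).reshape(-1)

    B = design_matrix(ds.bvecs)
    Binv = np.linalg.inv(B)
    d6 = np.zeros((s0.size, 6))
    if np.any(good):
        Y = -np.log(S[good] / s0[good, None]) / ds.bval   # (n, 6)
        d6[good] = Y @ Binv.T

    D = tensor_from_elements(d6)
    evals = np.linalg.eigvalsh(D)           # ascending, (n, 3)
    adc = np.mean(evals, axis=1)            # = trace/3
    lam = np.clip(evals, 0.0, None)         # clamp noise negatives before FA
    lam_norm = np.linalg.norm(lam, axis=1)
    dev = lam - lam.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.linalg.norm(dev, axis=1) / lam_norm
    fa = np.where(lam_norm > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)

    adc[~good] = np.nan
    fa[~good] = np.nan
    return TensorMap(
        tensor=d6.reshape(spatial + (6,)),
        adc=adc.reshape(spatial),
        fa=fa.reshape(spatial),
        mask=good.reshape(spatial),
    )


def roi_summary(tm: TensorMap, mask: np.ndarray) -> dict:
    """Masked mean ADC and FA with the voxel count used."""
    mask = np.asarray(mask, dtype=bool)
    sel = mask & tm.mask
    n = int(np.sum(sel))
    if n == 0:
        raise ValueError("ROI mask selects no fitted voxels")
    return {
        "mean_adc": float(np.mean(tm.adc[sel])),
        "mean_fa": float(np.mean(tm.fa[sel])),
        "n_voxels": n,
    }
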