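"""Image-quality and diffusion-model metrics.

Noise sigma from repeated b=0 acquisitions, SNR and angular CNR within
a mask, noise-normalized Tenengrad sharpness, NRMSE against a
reference, the two-sample Kolmogorov-Smirnov statistic for
distribution agreement, and a log-linear least-squares diffusion
tensor fit yielding FA/MD for bias evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class UndefinedMetricError(ValueError):
    """Metric undefined for the given inputs (e.g. zero noise sigma)."""


@dataclass
class MetricsReport:
    """Table-style summary of one reconstruction's quality metrics."""

    noise_sigma: float
    snr_b0: float
    snr_dwi_mean: float
    snr_dwi: list = field(default_factory=list)
    cnr_dwi: float = np.nan
    tenengrad_raw: float = np.nan
    tenengrad_normalized: float = np.nan
    nrmse: float = np.nan
    ks_fa: float = np.nan
    ks_md: float = np.nan
    delta_fa: float = np.nan
    delta_md: float = np.nan


def noise_std_from_repeats(
    b0_rep1: np.ndarray, b0_rep2: np.ndarray, mask: np.ndarray
) -> float:
    """Noise sigma from two repeats: std of their difference over sqrt(2)."""
    if b0_rep1.shape != b0_rep2.shape:
        raise ValueError("repeat shapes differ")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    diff = (np.asarray(b0_rep1) - np.asarray(b0_rep2))[mask]
    return float(np.std(diff) / np.sqrt(2.0))


def snr_and_cnr(
    b0: np.ndarray,
    dwis: np.ndarray,
    sigma: float,
    mask: np.ndarray,
) -> tuple[float, list[float], float]:
    """SNR of b=0 and each DWI, and the angular CNR, within a mask.

    SNR = mean signal / sigma.  Angular CNR = mean over the mask of the
    per-voxel standard deviation across diffusion directions, divided
    by sigma.
    """
    if sigma <= 0:
        raise UndefinedMetricError("noise sigma must be positive for SNR/CNR")
    mask = np.asarray(mask, dtype=bool)
    snr_b0 = float(np.mean(np.abs(b0)[mask]) / sigma)
    snr_dwi = [float(np.mean(np.abs(d)[mask]) / sigma) for d in dwis]
    angular_std = np.std(np.abs(np.asarray(dwis)), axis=0, ddof=0)
    cnr = float(np.mean(angular_std[mask]) / sigma)
    return snr_b0, snr_dwi, cnr


def tenengrad_sharpness(
    image: np.ndarray, mask: np.ndarray | None = None, sigma: float | None = None
) -> tuple[float, float]:
    """Gradient-magnitude sharpness, optionally noise-normalized.

    Raw value: mean over the mask of sqrt(sum of squared spatial
    gradients), central differences in the interior and one-sided at
    the borders.  Normalized value: raw / sigma (NaN if sigma absent).
    """
    img = np.abs(image) if np.iscomplexobj(image) else np.asarray(image, dtype=float)
    grads = np.gradient(img.astype(float))
    if img.ndim == 1:
        grads = [grads]
    gmag = np.sqrt(np.sum([g**2 for g in grads], axis=0))
    if mask is None:
        raw = float(np.mean(gmag))
    else:
        mask = np.asarray(mask, dtype=bool)
        raw = float(np.mean(gmag[mask]))
    norm = raw / sigma if sigma and sigma > 0 else np.nan
    return raw, norm


def nrmse(image: np.ndarray, reference: np.ndarray, mask: np.ndarray | None = None) -> float:
    """||image - reference|| / ||reference|| over an optional mask."""
    a = np.asarray(image)
    b = np.asarray(reference)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        a, b = a[m], b[m]
    ref_norm = np.linalg.norm(b)
    if ref_norm == 0:
        raise ValueError("zero reference norm")
    return float(np.linalg.norm(a - b) / ref_norm)


def ks_statistic(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sample KS statistic: max |ECDF_a - ECDF_b| over pooled support."""
    a = np.ravel(sample_a)
    b = np.ravel(sample_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


# ---------------------------------------------------------------------------
# diffusion tensor fit
# ---------------------------------------------------------------------------


def fit_dti(
    b0: np.ndarray,
    dwis: np.ndarray,
    bvecs: np.ndarray,
    b_value: float,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel log-linear least-squares diffusion tensor fit.

    Returns (FA, MD, tensor_field) with tensors in the same units as
    ``1/b_value``.  Needs at least six non-collinear directions plus
    the b=0 image; negative eigenvalues are clamped to zero for the FA
    computation.  Voxels outside the mask (or with non-positive signal)
    yield zeros.
    """
    dwis = np.asarray(dwis)
    bvecs = np.asarray(bvecs, dtype=float)
    if dwis.shape[0] < 6 or bvecs.shape[0] < 6:
        raise ValueError("need at least 6 diffusion directions")
    g = bvecs / np.linalg.norm(bvecs, axis=1, keepdims=True)
    design = -b_value * np.stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ],
        axis=1,
    )  # (n_dir, 6)
    rank = np.linalg.matrix_rank(design)
    if rank < 6:
        raise ValueError("diffusion directions are collinear/degenerate")
    shape = np.asarray(b0).shape
    mask = np.ones(shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    s0 = np.abs(np.asarray(b0))
    s = np.abs(dwis.reshape(dwis.shape[0], -1))
    valid = mask.ravel() & (s0.ravel() > 0) & np.all(s > 0, axis=0)
    logratio = np.zeros_like(s)
    logratio[:, valid] = np.log(s[:, valid] / s0.ravel()[None, valid])
    coef, *_ = np.linalg.lstsq(design, logratio, rcond=None)  # (6, n_vox)
    coef[:, ~valid] = 0.0
    dxx, dyy, dzz, dxy, dxz, dyz = coef
    tensors = np.zeros(shape + (3, 3))
    flatten = tensors.reshape(-1, 3, 3)
    flatten[:, 0, 0] = dxx
    flatten[:, 1, 1] = dyy
    flatten[:, 2, 2] = dzz
    flatten[:, 0, 1] = flatten[:, 1, 0] = dxy
    flatten[:, 0, 2] = flatten[:, 2, 0] = dxz
    flatten[:, 1, 2] = flatten[:, 2, 1] = dyz
    evals = np.linalg.eigvalsh(flatten)  # ascending, (n_vox, 3)
    md = evals.mean(axis=1)
    ev = np.clip(evals, 0.0, None)
    mean_ev = ev.mean(axis=1)
    num = np.sum((ev - mean_ev[:, None]) ** 2, axis=1)
    den = np.sum(ev**2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / np.where(den > 0, den, 1.0))
    fa = np.where(den > 0, fa, 0.0)
    fa[~valid] = 0.0
    md[~valid] = 0.0
    return fa.reshape(shape), md.reshape(shape), tensors
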