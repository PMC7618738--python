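"""Calibration: coil compression, SPIRiT kernel fitting, sensitivities.

The SPIRiT kernel expresses k-space self-consistency: every k-space
sample is predicted as a linear combination of its neighbors across all
coils (the center sample of the target coil excluded).  The kernel is
fit on a small fully sampled calibration region by ridge-regularized
least squares and applied on the full grid as a circular k-space
correlation, which is evaluated as a per-pixel coil-mixing matrix in
the image domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .fourier import fft2c, ifft2c, center_pad
from .synth import CoilModel, InvalidInputError


class InsufficientCalibrationError(ValueError):
    """Calibration region too small or degenerate for the requested fit."""


@dataclass
class SpiritKernel:
    """Calibrated k-space self-consistency kernel G.

    ``weights[c, c', dy, dx]`` is the contribution of coil ``c'`` at
    neighbor offset ``(dy-k//2, dx-k//2)`` to the prediction of coil
    ``c`` at the center; ``weights[c, c, k//2, k//2] == 0`` always.
    """

    weights: np.ndarray  # (n_coils, n_coils, k, k)
    tikhonov: float

    @property
    def n_coils(self) -> int:
        return self.weights.shape[0]

    @property
    def kernel_size(self) -> int:
        return self.weights.shape[-1]

    def image_mixing(self, shape: tuple[int, int]) -> np.ndarray:
        """Per-pixel coil-mixing matrices K (n_coils, n_coils, ny, nx).

        ``G x = F( einsum('cdyx,dyx->cyx', K, F^-1 x) )``: the k-space
        correlation by the kernel equals, for unitary centered
        transforms, a pointwise matrix multiply across coils in the
        image domain (circular boundary in k-space).
        """
        ny, nx = shape
        nc, k = self.n_coils, self.kernel_size
        h = np.zeros((nc, nc, ny, nx), dtype=complex)
        half = k // 2
        for dy in range(-half, half + 1):
            for dx in range(-half, half + 1):
                h[:, :, (ny // 2 - dy) % ny, (nx // 2 - dx) % nx] += self.weights[
                    :, :, dy + half, dx + half
                ]
        return np.sqrt(ny * nx) * ifft2c(h)


def apply_spirit(kernel_img: np.ndarray, x: np.ndarray) -> np.ndarray:
    """G x for multi-coil k-space ``x`` using precomputed image mixing maps."""
    m = ifft2c(x)
    return fft2c(np.einsum("cdyx,dyx->cyx", kernel_img, m))


def compress_coils(
    calibration: np.ndarray, n_target: int, *arrays: np.ndarray, coil_axis: int = 0
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """SVD coil compression fit on calibration data.

    Returns ``(compressed_calibration, matrix, [compressed arrays...])``
    where ``matrix`` has orthonormal columns (n_coils, n_target) and is
    applied consistently to every passed array along ``coil_axis``.
    """
    if n_target <= 0:
        raise InvalidInputError("n_target must be positive")
    nc = calibration.shape[0]
    if n_target > nc:
        raise InvalidInputError("n_target exceeds the number of coils")
    flat = calibration.reshape(nc, -1)
    u, _, _ = np.linalg.svd(flat, full_matrices=False)
    mat = u[:, :n_target]  # (nc, nt)

    def _apply(a: np.ndarray) -> np.ndarray:
        moved = np.moveaxis(a, coil_axis, 0)
        out = np.tensordot(mat.conj().T, moved, axes=(1, 0))
        return np.moveaxis(out, 0, coil_axis)

    comp_cal = np.tensordot(mat.conj().T, flat, axes=(1, 0)).reshape(
        (n_target,) + calibration.shape[1:]
    )
    return comp_cal, mat, [_apply(a) for a in arrays]


def calibrate_spirit_kernel(
    calibration: np.ndarray, kernel_size: int = 5, tikhonov: float = 0.01
) -> SpiritKernel:
    """Fit the SPIRiT kernel on a fully sampled calibration region.

    Every interior calibration sample of each coil is regressed on its
    ``kernel_size`` x ``kernel_size`` cross-coil neighborhood (own-coil
    center excluded), with ridge weight ``tikhonov * ||A||_2`` (spectral
    norm of the design matrix).
    """
    nc, wy, wx = calibration.shape
    k = kernel_size
    if np.linalg.norm(calibration) == 0:
        raise InsufficientCalibrationError("calibration data is all zero")
    n_pos = (wy - k + 1) * (wx - k + 1)
    n_unknown = nc * k * k - 1
    if n_pos < n_unknown:
        raise InsufficientCalibrationError(
            f"{n_pos} calibration equations for {n_unknown} unknowns"
        )
    # design matrix over all (coil, dy, dx) features
    win = sliding_window_view(calibration, (k, k), axis=(1, 2))  # (nc, py, px, k, k)
    a_full = win.transpose(1, 2, 0, 3, 4).reshape(n_pos, nc * k * k)
    center = k // 2
    lam = tikhonov * np.linalg.norm(a_full, 2)
    weights = np.zeros((nc, nc, k, k), dtype=complex)
    gram_full = a_full.conj().T @ a_full
    for c in range(nc):
        drop = c * k * k + center * k + center
        keep = np.delete(np.arange(nc * k * k), drop)
        gram = gram_full[np.ix_(keep, keep)]
        b = calibration[c, center : wy - center, center : wx - center].reshape(-1)
        rhs = a_full[:, keep].conj().T @ b
        w = np.linalg.solve(gram + lam**2 * np.eye(len(keep)), rhs)
        full_w = np.zeros(nc * k * k, dtype=complex)
        full_w[keep] = w
        weights[c] = full_w.reshape(nc, k, k)
    return SpiritKernel(weights=weights, tikhonov=tikhonov)


def estimate_sensitivities(
    calibration: np.ndarray,
    shape: tuple[int, int],
    rel_thresh: float = 0.05,
    apodize: bool = True,
) -> CoilModel:
    """Coil sensitivity maps from low-resolution calibration k-space.

    The apodized calibration region is zero-padded to the target grid,
    inverse-transformed, and divided by the root-sum-of-squares image;
    below ``rel_thresh`` of the peak RSS the division is clamped so the
    maps stay bounded outside the object.
    """
    if np.linalg.norm(calibration) == 0:
        raise InsufficientCalibrationError("calibration data is all zero")
    nc, wy, wx = calibration.shape
    cal = calibration
    if apodize:
        cal = cal * np.outer(np.hamming(wy), np.hamming(wx))[None]
    imgs = ifft2c(center_pad(cal, shape))
    rss = np.sqrt(np.sum(np.abs(imgs) ** 2, axis=0))
    floor = rel_thresh * rss.max()
    sens = imgs / np.maximum(rss, floor)[None]
    return CoilModel(sens=sens)
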