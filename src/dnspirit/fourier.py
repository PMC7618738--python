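"""Centered, unitary discrete Fourier transforms.

All k-space arrays in this package use a centered grid: the DC / k-space
center sample sits at index ``n // 2`` (0-based) along each transformed
axis, and transforms are orthonormal (``norm="ortho"``), so Parseval's
identity holds without scale factors and noise statistics are preserved
between domains.
"""

from __future__ import annotations

import numpy as np


def fft2c(img: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Image -> centered k-space over the last two axes (unitary)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(img, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifft2c(ksp: np.ndarray, axes: tuple[int, int] = (-2, -1)) -> np.ndarray:
    """Centered k-space -> image over the last two axes (unitary)."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(ksp, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def fft1c(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )


def ifft1c(x: np.ndarray, axis: int = -1) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"),
        axes=axis,
    )


def center_crop(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Crop the trailing axes of ``arr`` to ``shape`` around the k-space center."""
    out = arr
    for ax, n in zip(range(arr.ndim - len(shape), arr.ndim), shape):
        size = out.shape[ax]
        start = size // 2 - n // 2
        out = np.take(out, np.arange(start, start + n), axis=ax)
    return out


def center_pad(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Zero-pad the trailing axes of ``arr`` to ``shape`` around the k-space center."""
    ndim_lead = arr.ndim - len(shape)
    pad = [(0, 0)] * ndim_lead
    for ax, n in zip(range(ndim_lead, arr.ndim), shape):
        size = arr.shape[ax]
        if n < size:
            raise ValueError("center_pad target smaller than input")
        before = n // 2 - size // 2
        pad.append((before, n - size - before))
    return np.pad(arr, pad)
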