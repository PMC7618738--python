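"""Denoiser plug-in contract and a built-in locally-low-rank denoiser.

The reconstruction treats the denoiser as a black box Phi mapping an
image (magnitude or complex) to a denoised image of the same shape.
Denoisers register by id; third-party methods can attach through the
same contract.  The built-in ``llr`` denoiser performs sliding-patch
SVD hard thresholding at the Marchenko-Pastur noise floor — the
random-matrix principle behind PCA-based diffusion-MRI denoisers —
applied either to a single 2D image (patch-as-matrix) or to an image
stack (Casorati matrix of patch pixels x images).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np


class ContractViolationError(RuntimeError):
    """A denoiser plug-in broke the shape/validity contract."""


class UnknownDenoiserError(KeyError):
    """No denoiser registered under the requested id."""


@dataclass(frozen=True)
class DenoiserSpec:
    """A registered denoiser: callable + what it accepts.

    ``fn(image, sigma_hint, **options) -> image`` must be shape
    preserving, deterministic given inputs/options, and finite for
    finite input.  ``accepts`` is "magnitude" or "complex"; a
    magnitude-only denoiser applied to complex data sees ``|image|``
    and the input phase is restored afterwards.
    """

    id: str
    fn: Callable[..., np.ndarray]
    accepts: str = "complex"
    options: dict = field(default_factory=dict)


_REGISTRY: dict[str, DenoiserSpec] = {}


def register_denoiser(spec: DenoiserSpec) -> None:
    _REGISTRY[spec.id] = spec


def get_denoiser(denoiser_id: str) -> DenoiserSpec:
    try:
        return _REGISTRY[denoiser_id]
    except KeyError:
        raise UnknownDenoiserError(
            f"no denoiser registered under {denoiser_id!r}; "
            f"available: {sorted(_REGISTRY)}"
        ) from None


def apply_denoiser(
    spec: DenoiserSpec | str, image: np.ndarray, sigma_hint: float | None = None
) -> np.ndarray:
    """Run a denoiser under the plug-in contract (shape guard included)."""
    if isinstance(spec, str):
        spec = get_denoiser(spec)
    x = image
    phase = None
    if spec.accepts == "magnitude" and np.iscomplexobj(image):
        phase = np.exp(1j * np.angle(image))
        x = np.abs(image)
    out = spec.fn(x, sigma_hint=sigma_hint, **spec.options)
    out = np.asarray(out)
    if out.shape != x.shape:
        raise ContractViolationError(
            f"denoiser {spec.id!r} changed shape {x.shape} -> {out.shape}"
        )
    if not np.all(np.isfinite(out.view(float))):
        raise ContractViolationError(f"denoiser {spec.id!r} produced non-finite output")
    if phase is not None:
        out = out * phase
    return out


# ---------------------------------------------------------------------------
# built-ins
# ---------------------------------------------------------------------------


def identity_denoiser(image: np.ndarray, sigma_hint: float | None = None) -> np.ndarray:
    return image


def _mp_threshold(m: int, n: int, sigma: float) -> float:
    """Singular-value noise floor of an m x n i.i.d. noise matrix:
    the Marchenko-Pastur bulk edge sigma * (sqrt(m) + sqrt(n))."""
    return sigma * (np.sqrt(m) + np.sqrt(n))


def _estimate_sigma_mad(image: np.ndarray) -> float:
    """Robust noise scale from the finest diagonal detail residual."""
    d = image[1:, 1:] - image[1:, :-1] - image[:-1, 1:] + image[:-1, :-1]
    med = np.median(np.abs(d - np.median(d.real) - (1j * np.median(d.imag) if np.iscomplexobj(d) else 0)))
    return float(med / 0.6745 / 2.0)


def denoise_llr(
    image: np.ndarray,
    sigma_hint: float | None = None,
    patch: int = 8,
    stride: int = 4,
    threshold_scale: float = 1.0,
) -> np.ndarray:
    """Locally-low-rank denoising by patchwise SVD hard thresholding.

    For a 2D image each ``patch`` x ``patch`` block is treated as a
    matrix; for a stack (n_images, ny, nx) the Casorati matrix
    (patch-pixels x images) is used.  Singular values below the
    Marchenko-Pastur noise floor (scaled by ``threshold_scale``) are
    zeroed; overlapping reconstructions are averaged.
    """
    arr = np.asarray(image)
    stacked = arr.ndim == 3
    ny, nx = arr.shape[-2:]
    if patch > min(ny, nx):
        raise ValueError("patch larger than image")
    sigma = _estimate_sigma_mad(arr[0] if stacked else arr) if sigma_hint is None else sigma_hint
    out = np.zeros_like(arr, dtype=complex if np.iscomplexobj(arr) else float)
    weight = np.zeros((ny, nx))
    ys = list(range(0, ny - patch + 1, stride))
    xs = list(range(0, nx - patch + 1, stride))
    if ys[-1] != ny - patch:
        ys.append(ny - patch)
    if xs[-1] != nx - patch:
        xs.append(nx - patch)
    for y0 in ys:
        for x0 in xs:
            blk = arr[..., y0 : y0 + patch, x0 : x0 + patch]
            if stacked:
                mat = blk.reshape(arr.shape[0], -1).T  # (pixels, images)
            else:
                mat = blk
            u, s, vh = np.linalg.svd(mat, full_matrices=False)
            tau = threshold_scale * _mp_threshold(*mat.shape, sigma)
            s = np.where(s > tau, s, 0.0)
            rec = (u * s) @ vh
            if stacked:
                rec = rec.T.reshape(blk.shape)
            out[..., y0 : y0 + patch, x0 : x0 + patch] += rec
            weight[y0 : y0 + patch, x0 : x0 + patch] += 1.0
    out /= weight
    if not np.iscomplexobj(arr):
        out = out.real
    return out


register_denoiser(DenoiserSpec(id="identity", fn=identity_denoiser, accepts="complex"))
register_denoiser(DenoiserSpec(id="llr", fn=denoise_llr, accepts="complex"))
register_denoiser(DenoiserSpec(id="llr_magnitude", fn=denoise_llr, accepts="magnitude"))
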