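"""Multi-shot SPIRiT reconstruction with a plug-and-play denoiser prior.

The unknown is the fully sampled multi-coil k-space ``x`` of one 2D
plane.  Each shot ``i`` contributes a data-consistency block
``D_i F P_i F^-1 x = y_i`` (``P_i`` the unit-magnitude motion-induced
phase of that shot), the calibrated SPIRiT kernel contributes the
self-consistency penalty ``lambda1 ||(G - I) x||^2``, and the
plug-and-play prior penalizes distance to the latest denoised image,
``lambda2 ||F^-1 x - z||^2``.  The inner least-squares problem is
solved by conjugate gradients on the normal equations; the outer loop
alternates the CG solve with a denoising step (the first outer
iteration, with ``lambda2 = 0``, is a standard phase-corrected SPIRiT
reconstruction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .calib import SpiritKernel
from .denoise import DenoiserSpec, apply_denoiser, get_denoiser
from .fourier import fft2c, ifft2c, center_pad
from .synth import CoilModel, InvalidInputError, KSpaceShotSet, SamplingScheme


@dataclass
class PhaseMaps:
    """Per-shot image-space phase, unit magnitude, referenced to shot 0."""

    maps: np.ndarray  # complex (n_shots, ny, nx), |maps| = 1

    def __post_init__(self) -> None:
        mag = np.abs(self.maps)
        if not np.allclose(mag, 1.0, atol=1e-6):
            raise InvalidInputError("phase maps must be unit magnitude")

    @property
    def n_shots(self) -> int:
        return self.maps.shape[0]


@dataclass
class ReconConfig:
    """Weights and solver settings for the iterative reconstruction."""

    lambda1: float = 10.0  # SPIRiT self-consistency weight
    lambda2: float = 2.0  # denoiser prior weight
    n_outer: int = 5
    cg_tol: float = 1e-6
    cg_max_iter: int = 100
    denoiser: str | DenoiserSpec = "llr"
    sigma_hint: float | None = None
    recombination: str = "magnitude_sos"  # or "complex_sense"

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise InvalidInputError("lambda weights must be >= 0")
        if self.n_outer < 1:
            raise InvalidInputError("n_outer must be >= 1")
        if self.recombination not in ("magnitude_sos", "complex_sense"):
            raise InvalidInputError("recombination must be magnitude_sos or complex_sense")


@dataclass
class ReconResult:
    """Final k-space, combined image, and solver diagnostics."""

    kspace: np.ndarray  # (n_coils, ny, nx)
    image: np.ndarray  # combined plane image
    coil_images: np.ndarray  # (n_coils, ny, nx)
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# phase estimation
# ---------------------------------------------------------------------------


def estimate_phase_maps(
    navigators: np.ndarray, shape: tuple[int, int], window: int | None = None
) -> PhaseMaps:
    """Shot phase maps from low-resolution navigators.

    The navigator k-space is smoothed by a Hamming window (default: the
    full navigator extent), zero-padded to the image grid, and
    inverse-transformed; the relative phase of shot ``i`` against shot
    0 is taken from the coil-combined cross-correlation
    ``sum_c m_ic conj(m_0c)``, which cancels coil and object phase.
    """
    if navigators is None or navigators.ndim != 4:
        raise InvalidInputError("need one (n_coils, w, w) navigator per shot")
    n_shots, n_coils, wy, wx = navigators.shape
    w = wy if window is None else window
    taper = np.outer(np.hamming(w), np.hamming(w))
    if (wy, wx) != (w, w):
        raise InvalidInputError("navigator window size mismatch")
    imgs = ifft2c(center_pad(navigators * taper[None, None], shape))
    ref = imgs[0]
    maps = np.empty((n_shots,) + tuple(shape), dtype=complex)
    maps[0] = 1.0
    for i in range(1, n_shots):
        cross = np.sum(imgs[i] * np.conj(ref), axis=0)
        maps[i] = np.exp(1j * np.angle(cross))
    return PhaseMaps(maps=maps)


# ---------------------------------------------------------------------------
# linear operators and CG
# ---------------------------------------------------------------------------


def _forward_shot(x: np.ndarray, pmap: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """A_i x = D_i F (P_i . F^-1 x) for one shot."""
    img = ifft2c(x)
    return fft2c(pmap[None] * img) * mask[None, :, None]


def _adjoint_shot(y: np.ndarray, pmap: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """A_i^H y."""
    img = ifft2c(y * mask[None, :, None])
    return fft2c(np.conj(pmap)[None] * img)


def hermitian_cg(
    op: Callable[[np.ndarray], np.ndarray],
    b: np.ndarray,
    x0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, dict]:
    """Conjugate gradients for a Hermitian positive (semi-)definite op.

    Stops at relative residual ``tol`` (against ||b||) or ``max_iter``.
    Returns the iterate and a diagnostics dict with the residual-norm
    log; a residual increase beyond 10x the best seen is flagged as
    divergence in the diagnostics rather than raised.
    """
    if not np.all(np.isfinite(b.view(float))):
        raise InvalidInputError("non-finite right-hand side")
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return np.zeros_like(b), {"iterations": 0, "residuals": [0.0], "diverged": False}
    x = np.zeros_like(b) if x0 is None else x0.copy()
    r = b - op(x)
    p = r.copy()
    rs = np.vdot(r, r).real
    residuals = [np.sqrt(rs) / bnorm]
    diverged = False
    it = 0
    for it in range(1, max_iter + 1):
        ap = op(p)
        denom = np.vdot(p, ap).real
        if denom <= 0:
            break
        alpha = rs / denom
        x += alpha * p
        r -= alpha * ap
        rs_new = np.vdot(r, r).real
        residuals.append(np.sqrt(rs_new) / bnorm)
        if residuals[-1] < tol:
            rs = rs_new
            break
        if residuals[-1] > 10.0 * min(residuals):
            diverged = True
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x, {"iterations": it, "residuals": residuals, "diverged": diverged}


class ShotSystem:
    """Normal-equation operator of the stacked multi-shot problem."""

    def __init__(
        self,
        data: np.ndarray,  # (n_shots, n_coils, ny, nx)
        masks: np.ndarray,  # (n_shots, ny) line masks
        phases: PhaseMaps,
        kernel: SpiritKernel | None,
        lambda1: float,
        lambda2: float,
    ) -> None:
        if not np.all(np.isfinite(data.view(float))):
            raise InvalidInputError("non-finite k-space data")
        self.data = data
        self.masks = masks.astype(float)
        self.phases = phases
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        shape = data.shape[2:]
        if kernel is not None and lambda1 > 0:
            k_img = kernel.image_mixing(shape)
            nc = kernel.n_coils
            gmi = k_img - np.eye(nc)[:, :, None, None]  # (G - I) mixing
            # precompute (G-I)^H (G-I) per pixel
            self.normal_mix = np.einsum("tcyx,tdyx->cdyx", np.conj(gmi), gmi)
            self.gmi = gmi
        else:
            self.normal_mix = None
            self.gmi = None

    def forward_data(self, x: np.ndarray) -> np.ndarray:
        return np.stack(
            [_forward_shot(x, self.phases.maps[i], self.masks[i]) for i in range(len(self.data))]
        )

    def normal(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x)
        for i in range(len(self.data)):
            out += _adjoint_shot(
                _forward_shot(x, self.phases.maps[i], self.masks[i]),
                self.phases.maps[i],
                self.masks[i],
            )
        if self.normal_mix is not None:
            m = ifft2c(x)
            out += self.lambda1 * fft2c(np.einsum("cdyx,dyx->cyx", self.normal_mix, m))
        if self.lambda2 > 0:
            out += self.lambda2 * x  # F^-1 is unitary
        return out

    def rhs(self, z_multi: np.ndarray | None = None) -> np.ndarray:
        b = np.zeros(self.data.shape[1:], dtype=complex)
        for i in range(len(self.data)):
            b += _adjoint_shot(self.data[i], self.phases.maps[i], self.masks[i])
        if self.lambda2 > 0 and z_multi is not None:
            b += self.lambda2 * fft2c(z_multi)
        return b

    def objective(self, x: np.ndarray, z_multi: np.ndarray | None) -> float:
        """Value of the stacked least-squares objective at x."""
        val = 0.0
        for i in range(len(self.data)):
            r = _forward_shot(x, self.phases.maps[i], self.masks[i]) - self.data[i]
            val += float(np.vdot(r, r).real)
        if self.gmi is not None:
            g = np.einsum("cdyx,dyx->cyx", self.gmi, ifft2c(x))
            val += self.lambda1 * float(np.vdot(g, g).real)
        if z_multi is not None and self.lambda2 > 0:
            d = ifft2c(x) - z_multi
            val += self.lambda2 * float(np.vdot(d, d).real)
        return val


def cg_solve_normal(
    data: np.ndarray,
    masks: np.ndarray,
    phases: PhaseMaps,
    kernel: SpiritKernel | None,
    lambda1: float,
    lambda2: float = 0.0,
    z_prev: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    cg_tol: float = 1e-6,
    cg_max_iter: int = 100,
) -> tuple[np.ndarray, dict]:
    """Solve the normal equations of the stacked shot/SPIRiT/prior system.

    ``z_prev`` is the denoised multi-coil image entering the prior term
    (image domain).  Returns the multi-coil k-space solution and CG
    diagnostics.
    """
    system = ShotSystem(data, masks, phases, kernel, lambda1, lambda2)
    b = system.rhs(z_prev)
    x, info = hermitian_cg(system.normal, b, x0=x0, tol=cg_tol, max_iter=cg_max_iter)
    info["objective"] = system.objective(x, z_prev)
    return x, info


# ---------------------------------------------------------------------------
# coil combination and high-level reconstructions
# ---------------------------------------------------------------------------


def combine_coils(
    images: np.ndarray, sens: np.ndarray | None = None, mode: str = "sos"
) -> np.ndarray:
    """Combine multi-coil images: root-sum-of-squares or SENSE-weighted."""
    if mode == "sos":
        return np.sqrt(np.sum(np.abs(images) ** 2, axis=0))
    if mode == "sense":
        if sens is None:
            raise InvalidInputError("sense combination requires sensitivity maps")
        denom = np.sum(np.abs(sens) ** 2, axis=0)
        if denom.max() == 0:
            raise InvalidInputError("all-zero sensitivities")
        return np.sum(np.conj(sens) * images, axis=0) / np.maximum(denom, 1e-12 * denom.max())
    raise InvalidInputError(f"unknown combination mode {mode!r}")


def spirit_recon(
    shotset: KSpaceShotSet,
    phases: PhaseMaps,
    kernel: SpiritKernel,
    config: ReconConfig | None = None,
    sens: np.ndarray | None = None,
) -> ReconResult:
    """Phase-corrected multi-shot SPIRiT (no denoiser prior)."""
    config = config or ReconConfig()
    x, info = cg_solve_normal(
        shotset.data,
        shotset.masks,
        phases,
        kernel,
        config.lambda1,
        lambda2=0.0,
        cg_tol=config.cg_tol,
        cg_max_iter=config.cg_max_iter,
    )
    coil_imgs = ifft2c(x)
    mode = "sos" if config.recombination == "magnitude_sos" else "sense"
    image = combine_coils(coil_imgs, sens=sens, mode=mode)
    return ReconResult(
        kspace=x,
        image=image,
        coil_images=coil_imgs,
        diagnostics={"cg": [info], "objective": [info["objective"]]},
    )


def dnspirit_recon(
    shotset: KSpaceShotSet,
    phases: PhaseMaps,
    kernel: SpiritKernel,
    sens: np.ndarray,
    config: ReconConfig | None = None,
) -> ReconResult:
    """Denoiser-regularized multi-shot SPIRiT (plug-and-play outer loop).

    Iteration 1 is plain SPIRiT; afterwards the coil-combined image is
    denoised and re-expanded through the sensitivities (magnitude path:
    denoise the sum-of-squares magnitude, multiply by the coil maps;
    complex path: sensitivity-combine, denoise the complex image,
    re-multiply), then the CG solve is repeated with the prior active.
    """
    config = config or ReconConfig()
    spec = config.denoiser if isinstance(config.denoiser, DenoiserSpec) else get_denoiser(config.denoiser)
    first = spirit_recon(shotset, phases, kernel, config, sens=sens)
    x = first.kspace
    cg_log = list(first.diagnostics["cg"])
    objectives = [first.diagnostics["objective"][0]]
    z_multi = None
    for _ in range(1, config.n_outer):
        coil_imgs = ifft2c(x)
        if config.recombination == "magnitude_sos":
            combined = combine_coils(coil_imgs, mode="sos")
            z = apply_denoiser(spec, combined, sigma_hint=config.sigma_hint)
            z_multi = sens * z[None]
        else:
            combined = combine_coils(coil_imgs, sens=sens, mode="sense")
            z = apply_denoiser(spec, combined, sigma_hint=config.sigma_hint)
            z_multi = sens * z[None]
        x, info = cg_solve_normal(
            shotset.data,
            shotset.masks,
            phases,
            kernel,
            config.lambda1,
            lambda2=config.lambda2,
            z_prev=z_multi,
            x0=x,
            cg_tol=config.cg_tol,
            cg_max_iter=config.cg_max_iter,
        )
        cg_log.append(info)
        objectives.append(info["objective"])
    coil_imgs = ifft2c(x)
    mode = "sos" if config.recombination == "magnitude_sos" else "sense"
    image = combine_coils(coil_imgs, sens=sens, mode=mode)
    return ReconResult(
        kspace=x,
        image=image,
        coil_images=coil_imgs,
        diagnostics={"cg": cg_log, "objective": objectives},
    )


# ---------------------------------------------------------------------------
# partial Fourier and retrospective under-sampling
# ---------------------------------------------------------------------------


def partial_fourier_fill(kspace: np.ndarray, pf: float, mode: str = "zp") -> np.ndarray:
    """Fill the unacquired early-ky partial-Fourier band.

    ``zp`` leaves it zero; ``cs`` copies conjugate-symmetric values
    after removing the zeroth-order (global) phase measured at the
    k-space center, then restores it.  Operates on the trailing
    (ky, kx) axes of any multi-coil stack.
    """
    if not (0.5 < pf <= 1.0):
        raise InvalidInputError("pf must be in (0.5, 1]")
    if mode not in ("zp", "cs"):
        raise InvalidInputError("mode must be 'zp' or 'cs'")
    ny, nx = kspace.shape[-2:]
    first = ny - int(np.ceil(pf * ny))
    out = kspace.copy()
    out[..., :first, :] = 0.0
    if mode == "zp" or first == 0:
        return out
    center = out[..., ny // 2, nx // 2]
    phase0 = np.exp(1j * np.angle(np.where(center == 0, 1.0, center)))
    demod = out * np.conj(phase0)[..., None, None]
    my = (ny - np.arange(ny)) % ny
    mx = (nx - np.arange(nx)) % nx
    mirrored = np.conj(demod[..., my[:, None], mx[None, :]])
    demod[..., :first, :] = mirrored[..., :first, :]
    return demod * phase0[..., None, None]


def retrospective_undersample(shotset: KSpaceShotSet, n_keep: int) -> KSpaceShotSet:
    """Keep an evenly spaced subset of the acquired segments."""
    n = shotset.n_shots
    if n_keep < 1 or n % n_keep != 0:
        raise InvalidInputError("n_keep must evenly divide the number of shots")
    step = n // n_keep
    idx = np.arange(0, n, step)
    old = shotset.scheme
    scheme = SamplingScheme(
        n_pe=old.n_pe,
        n_seg=old.n_seg,
        seg_indices=old.seg_indices[idx],
        pf=old.pf,
        ordering=old.ordering,
    )
    return KSpaceShotSet(
        data=shotset.data[idx],
        masks=shotset.masks[idx],
        navigators=shotset.navigators[idx],
        calibration=shotset.calibration,
        scheme=scheme,
        nav_window=shotset.nav_window,
    )
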