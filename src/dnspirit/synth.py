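"""Seeded generators for synthetic multi-shot, multi-coil diffusion data.

Everything a multi-shot parallel-imaging reconstruction needs can be
generated here deterministically from a seed: a brain-like complex
phantom with diffusion-tensor contrast, smooth coil sensitivity maps,
per-shot motion-induced phase fields, interleaved ky sampling schemes
(with optional partial Fourier and shot under-sampling), and the
resulting noisy k-space with navigators and a calibration scan.

The atomic simulation unit is a 2D (ky, kx) plane — mirroring a
reconstruction that operates per ky-kz plane after a 1D transform along
the fully sampled readout — so "image" below always means a 2D complex
array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier import fft2c, ifft2c, center_crop, center_pad


class InvalidInputError(ValueError):
    """Inconsistent shapes or out-of-domain generator parameters."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DigitalPhantom:
    """Ground-truth object: b=0 image, tensor field, and masks."""

    baseline: np.ndarray  # complex (ny, nx)
    tensor_field: np.ndarray  # (ny, nx, 3, 3) symmetric PSD, mm^2/s
    directions: np.ndarray  # (n_dir, 3) unit vectors
    b_value: float  # s/mm^2
    brain_mask: np.ndarray  # bool (ny, nx)
    wm_mask: np.ndarray  # bool (ny, nx)

    def dwi(self, direction: np.ndarray) -> np.ndarray:
        """Noise-free diffusion-weighted image along a unit direction."""
        g = np.asarray(direction, dtype=float)
        if abs(np.linalg.norm(g) - 1.0) > 1e-6:
            raise InvalidInputError("diffusion direction must be a unit vector")
        atten = np.exp(-self.b_value * np.einsum("i,yxij,j->yx", g, self.tensor_field, g))
        return self.baseline * atten

    @property
    def volumes(self) -> list[np.ndarray]:
        """[b=0, DWI_1, ..., DWI_n] noise-free images."""
        return [self.baseline] + [self.dwi(g) for g in self.directions]


@dataclass
class CoilModel:
    """Smooth complex receive sensitivities, RSS-normalized in support."""

    sens: np.ndarray  # complex (n_coils, ny, nx)

    @property
    def n_coils(self) -> int:
        return self.sens.shape[0]


@dataclass
class ShotPhaseModel:
    """Per-shot smooth motion-induced phase fields (rad); shot 0 is zero."""

    phases: np.ndarray  # real (n_shots, ny, nx)
    amplitude: float
    seed: int | None = None

    @property
    def n_shots(self) -> int:
        return self.phases.shape[0]

    def complex_maps(self) -> np.ndarray:
        """exp(i * phase), the unit-magnitude maps entering the forward model."""
        return np.exp(1j * self.phases)


@dataclass
class SamplingScheme:
    """Interleaved ky segmentation with partial Fourier and shot selection.

    Segment ``s`` owns ky lines ``{s, s+n_seg, ...}``; the acquired
    segments are an evenly spaced subset of size ``n_acq``; partial
    Fourier removes the early-ky band (lines below ``first_line``).
    """

    n_pe: int
    n_seg: int
    seg_indices: np.ndarray  # acquired segment ids, evenly spaced
    pf: float
    ordering: str = "ky-kz"

    def __post_init__(self) -> None:
        self.seg_indices = np.asarray(self.seg_indices, dtype=int)

    @property
    def n_shots(self) -> int:
        return len(self.seg_indices)

    @property
    def r_eff(self) -> float:
        return self.n_seg / self.n_shots

    @property
    def first_line(self) -> int:
        return self.n_pe - int(np.ceil(self.pf * self.n_pe))

    def line_masks(self) -> np.ndarray:
        """Boolean (n_shots, n_pe): which ky lines each shot acquires."""
        lines = np.arange(self.n_pe)
        masks = np.stack(
            [(lines % self.n_seg == s) & (lines >= self.first_line) for s in self.seg_indices]
        )
        return masks

    def time_stamps(self, es: float = 1.0) -> np.ndarray:
        """Per-(shot, line) acquisition times; NaN where not acquired.

        ``ky-kz`` ordering: echo index within the shot times the echo
        spacing.  ``kz-ky`` differs only across planes (a per-plane
        constant offset), so within one plane the stamps coincide.
        """
        masks = self.line_masks()
        stamps = np.full(masks.shape, np.nan)
        for i in range(self.n_shots):
            idx = np.nonzero(masks[i])[0]
            stamps[i, idx] = np.arange(len(idx)) * es
        return stamps


@dataclass
class KSpaceShotSet:
    """Acquired multi-shot, multi-coil k-space plus navigators/calibration."""

    data: np.ndarray  # complex (n_shots, n_coils, n_pe, n_x)
    masks: np.ndarray  # bool (n_shots, n_pe)
    navigators: np.ndarray  # complex (n_shots, n_coils, w, w)
    calibration: np.ndarray  # complex (n_coils, w, w), noise-free
    scheme: SamplingScheme
    nav_window: int = 32

    @property
    def n_shots(self) -> int:
        return self.data.shape[0]

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]

    @property
    def plane_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _axisymmetric_eigenvalues(md: float, fa: float) -> tuple[float, float]:
    """(lambda_parallel, lambda_perp) of an axially symmetric tensor with
    the requested mean diffusivity and fractional anisotropy (closed form)."""
    s = fa / np.sqrt(3.0 - 2.0 * fa**2)
    return md * (1.0 + 2.0 * s), md * (1.0 - s)


DEFAULT_DIRECTIONS = np.array(
    [
        [1.0, 1.0, 0.0],
        [1.0, -1.0, 0.0],
        [1.0, 0.0, 1.0],
        [1.0, 0.0, -1.0],
        [0.0, 1.0, 1.0],
        [0.0, 1.0, -1.0],
    ]
) / np.sqrt(2.0)


def make_phantom(
    shape: tuple[int, int] = (128, 128),
    n_directions: int = 6,
    b_value: float = 1000.0,
    fa_levels: tuple[float, ...] = (0.8, 0.4),
    seed: int = 0,
    md: float = 8.0e-4,
) -> DigitalPhantom:
    """Brain-like 2D phantom with diffusion-tensor contrast.

    Nested ellipses form the head/brain; concentric ring ribbons play
    the role of white-matter tracts, one per entry of ``fa_levels``,
    with the principal eigenvector following the ribbon tangent so the
    diffusion contrast is direction dependent.  Gray matter / background
    tissue is isotropic at mean diffusivity ``md`` (mm^2/s).  The
    baseline carries a smooth, seeded complex phase.
    """
    ny, nx = shape
    if min(ny, nx) < 32:
        raise InvalidInputError("phantom shape must be >= 32 per axis")
    if n_directions < 0:
        raise InvalidInputError("n_directions must be >= 0")
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    u = (y - cy) / (0.45 * ny)
    v = (x - cx) / (0.42 * nx)
    r2 = u**2 + v**2
    brain = r2 <= 1.0
    intensity = np.where(brain, 1.0, 0.0)
    # cortical rim slightly brighter, deep structures darker
    intensity += np.where((r2 > 0.72) & brain, 0.25, 0.0)
    intensity -= np.where(r2 < 0.08, 0.35, 0.0)

    # white-matter ring ribbons with tangential fibers
    radius = np.sqrt(r2)
    wm = np.zeros(shape, dtype=bool)
    tensors = np.zeros((ny, nx, 3, 3))
    iso = np.eye(3) * md
    tensors[...] = iso
    ring_centers = np.linspace(0.35, 0.62, num=max(len(fa_levels), 1))
    theta = np.arctan2(u, v)
    for fa, rc in zip(fa_levels, ring_centers):
        ribbon = brain & (np.abs(radius - rc) < 0.055)
        lam_par, lam_perp = _axisymmetric_eigenvalues(md, fa)
        # tangent of the ring: (-sin t, cos t) in (y, x) plane
        e1 = np.stack([-np.sin(theta), np.cos(theta), np.zeros_like(theta)], axis=-1)
        e2 = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=-1)
        e3 = np.zeros_like(e1)
        e3[..., 2] = 1.0
        D = (
            lam_par * np.einsum("yxi,yxj->yxij", e1, e1)
            + lam_perp * np.einsum("yxi,yxj->yxij", e2, e2)
            + lam_perp * np.einsum("yxi,yxj->yxij", e3, e3)
        )
        tensors[ribbon] = D[ribbon]
        wm |= ribbon
        intensity = np.where(ribbon, 0.85, intensity)

    # smooth seeded background phase
    phase = _bandlimited_field(shape, window=6, rng=rng) * 0.8
    baseline = intensity * np.exp(1j * phase)

    directions = DEFAULT_DIRECTIONS[:n_directions] if n_directions <= 6 else _sphere_dirs(n_directions)
    return DigitalPhantom(
        baseline=baseline.astype(complex),
        tensor_field=tensors,
        directions=directions,
        b_value=b_value,
        brain_mask=brain,
        wm_mask=wm,
    )


def _sphere_dirs(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden-spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + 5**0.5)
    th = golden * i
    return np.stack([np.sin(phi) * np.cos(th), np.sin(phi) * np.sin(th), np.cos(phi)], axis=1)


def _bandlimited_field(
    shape: tuple[int, int], window: int, rng: np.random.Generator
) -> np.ndarray:
    """Real random field whose spectrum lives in a central window,
    normalized to unit maximum magnitude."""
    ny, nx = shape
    coef = rng.standard_normal((window, window)) + 1j * rng.standard_normal((window, window))
    taper = np.outer(np.hamming(window), np.hamming(window))
    ksp = center_pad(coef * taper, (ny, nx))
    f = ifft2c(ksp).real
    m = np.abs(f).max()
    return f / m if m > 0 else f


def make_sensitivities(
    shape: tuple[int, int] = (128, 128),
    n_coils: int = 8,
    smoothness: int = 12,
    seed: int = 0,
) -> CoilModel:
    """Smooth complex coil maps on a ring, RSS-normalized.

    Each coil is a Gaussian reception profile centered on a ring around
    the FOV with a low-order phase roll; maps are band-limited to a
    central ``smoothness`` x ``smoothness`` k-space window before
    normalization, so their spectra are concentrated far below the
    calibration-region size.
    """
    ny, nx = shape
    if n_coils < 1:
        raise InvalidInputError("n_coils must be >= 1")
    if n_coils == 1:
        return CoilModel(sens=np.ones((1, ny, nx), dtype=complex))
    rng = np.random.default_rng(seed)
    y, x = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    maps = np.empty((n_coils, ny, nx), dtype=complex)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.1, 0.1)
        py = cy + 0.55 * ny * np.sin(ang)
        px = cx + 0.55 * nx * np.cos(ang)
        d2 = ((y - py) / (0.6 * ny)) ** 2 + ((x - px) / (0.6 * nx)) ** 2
        mag = np.exp(-d2)
        ph = (
            2 * np.pi * (0.3 * rng.standard_normal()) * (y - cy) / ny
            + 2 * np.pi * (0.3 * rng.standard_normal()) * (x - cx) / nx
            + rng.uniform(0, 2 * np.pi)
        )
        maps[c] = mag * np.exp(1j * ph)
    # band-limit to the central window
    ksp = fft2c(maps)
    keep = np.zeros((ny, nx))
    keep[
        ny // 2 - smoothness // 2 : ny // 2 + (smoothness + 1) // 2,
        nx // 2 - smoothness // 2 : nx // 2 + (smoothness + 1) // 2,
    ] = np.outer(np.hamming(smoothness), np.hamming(smoothness))
    maps = ifft2c(ksp * keep)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0))
    maps = maps / np.maximum(rss, 1e-12 * rss.max())
    return CoilModel(sens=maps)


def make_shot_phases(
    shape: tuple[int, int],
    n_shots: int,
    amplitude: float = 1.5,
    seed: int = 0,
    window: int = 8,
) -> ShotPhaseModel:
    """Per-shot smooth random phase fields, shot 0 as zero-phase reference.

    Fields are band-limited to a central ``window`` x ``window`` k-space
    support (well inside a 32x32 navigator window even after the
    exponential map) and scaled so ``max |phase| = amplitude`` (rad).
    """
    if amplitude < 0:
        raise InvalidInputError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    phases = np.zeros((n_shots,) + tuple(shape))
    for i in range(1, n_shots):
        phases[i] = amplitude * _bandlimited_field(shape, window, rng)
    return ShotPhaseModel(phases=phases, amplitude=amplitude, seed=seed)


def make_sampling_scheme(
    n_pe: int,
    n_seg: int,
    n_acq: int | None = None,
    pf: float = 1.0,
    ordering: str = "ky-kz",
) -> SamplingScheme:
    """Evenly spaced acquired segments within an interleaved ky scheme."""
    n_acq = n_seg if n_acq is None else n_acq
    if not 1 <= n_acq <= n_seg:
        raise InvalidInputError("require 1 <= n_acq <= n_seg")
    if n_seg % n_acq != 0:
        raise InvalidInputError("n_acq must divide n_seg for even spacing")
    if not (0.5 < pf <= 1.0):
        raise InvalidInputError("pf must be in (0.5, 1]")
    if ordering not in ("ky-kz", "kz-ky"):
        raise InvalidInputError("ordering must be 'ky-kz' or 'kz-ky'")
    step = n_seg // n_acq
    return SamplingScheme(
        n_pe=n_pe,
        n_seg=n_seg,
        seg_indices=np.arange(0, n_seg, step),
        pf=pf,
        ordering=ordering,
    )


def encode_acquisition(
    image: np.ndarray,
    coils: CoilModel,
    phases: ShotPhaseModel,
    scheme: SamplingScheme,
    noise_sigma: float = 0.0,
    seed: int = 0,
    nav_window: int = 32,
    calibration_image: np.ndarray | None = None,
) -> KSpaceShotSet:
    """Forward-encode one image into a multi-shot k-space acquisition.

    Per shot: ``y_i = D_i F (P_i * S * image) + n`` with i.i.d. complex
    Gaussian noise of total standard deviation ``noise_sigma`` per
    sample (unitary transforms, so image- and k-space noise levels
    coincide).  Navigators are the fully sampled central
    ``nav_window`` k-space of the same phase-bearing coil images (noisy
    at the same sigma); the calibration scan is the noise-free central
    k-space of the (phase-free) calibration image, by default the image
    itself.
    """
    ny, nx = image.shape
    if coils.sens.shape[1:] != (ny, nx):
        raise InvalidInputError("coil maps do not match image shape")
    if phases.phases.shape[0] != scheme.n_shots or phases.phases.shape[1:] != (ny, nx):
        raise InvalidInputError("phase maps do not match shots/shape")
    if scheme.n_pe != ny:
        raise InvalidInputError("sampling scheme n_pe must equal image ky size")
    rng = np.random.default_rng(seed)
    n_coils = coils.n_coils
    p = phases.complex_maps()
    masks = scheme.line_masks()
    data = np.zeros((scheme.n_shots, n_coils, ny, nx), dtype=complex)
    navs = np.zeros((scheme.n_shots, n_coils, nav_window, nav_window), dtype=complex)
    for i in range(scheme.n_shots):
        coil_imgs = p[i][None] * coils.sens * image[None]
        ksp = fft2c(coil_imgs)
        if noise_sigma > 0:
            noise = (
                rng.standard_normal(ksp.shape) + 1j * rng.standard_normal(ksp.shape)
            ) * (noise_sigma / np.sqrt(2.0))
            ksp = ksp + noise
        data[i] = ksp * masks[i][None, :, None]
        nav_full = fft2c(p[i][None] * coils.sens * image[None])
        if noise_sigma > 0:
            nn = (
                rng.standard_normal(nav_full.shape) + 1j * rng.standard_normal(nav_full.shape)
            ) * (noise_sigma / np.sqrt(2.0))
            nav_full = nav_full + nn
        navs[i] = center_crop(nav_full, (nav_window, nav_window))
    calib_img = image if calibration_image is None else calibration_image
    calib = center_crop(fft2c(coils.sens * calib_img[None]), (nav_window, nav_window))
    return KSpaceShotSet(
        data=data,
        masks=masks,
        navigators=navs,
        calibration=calib,
        scheme=scheme,
        nav_window=nav_window,
    )


# ---------------------------------------------------------------------------
# reference fixture
# ---------------------------------------------------------------------------


@dataclass
class DiffusionFixture:
    """A complete synthetic diffusion study on one plane.

    ``shotsets`` holds [b0 repeat 1, b0 repeat 2, DWI_1..n]; the two b=0
    repeats share the truth image but carry independent noise, enabling
    noise-sigma estimation from repeats.  b=0 volumes are encoded
    without motion phases (no diffusion gradients, negligible motion
    sensitivity); each DWI volume gets independent per-shot phases.
    """

    phantom: DigitalPhantom
    coils: CoilModel
    scheme: SamplingScheme
    shotsets: list[KSpaceShotSet]
    phase_models: list[ShotPhaseModel]
    truth_images: list[np.ndarray]
    noise_sigma: float
    seed: int


def make_diffusion_fixture(
    shape: tuple[int, int] = (128, 128),
    n_coils: int = 8,
    n_seg: int = 6,
    n_acq: int | None = None,
    pf: float = 1.0,
    snr: float = 5.0,
    phase_amplitude: float = 1.5,
    n_directions: int = 6,
    seed: int = 7,
    nav_window: int = 32,
) -> DiffusionFixture:
    """The standard end-to-end test object (defaults: 128^2, 8 coils,
    6 shots, SNR 5, seed 7).

    ``snr`` is mean brain-mask baseline magnitude over the per-sample
    complex noise sigma; ``snr=inf`` or ``<=0`` disables noise.
    """
    phantom = make_phantom(shape, n_directions=n_directions, seed=seed)
    coils = make_sensitivities(shape, n_coils=n_coils, seed=seed + 1)
    scheme = make_sampling_scheme(shape[0], n_seg, n_acq=n_acq, pf=pf)
    mean_sig = float(np.mean(np.abs(phantom.baseline)[phantom.brain_mask]))
    sigma = 0.0 if (snr <= 0 or not np.isfinite(snr)) else mean_sig / snr
    zero_phase = ShotPhaseModel(
        phases=np.zeros((scheme.n_shots,) + tuple(shape)), amplitude=0.0, seed=seed
    )
    truth = [phantom.baseline, phantom.baseline] + [
        phantom.dwi(g) for g in phantom.directions
    ]
    shotsets: list[KSpaceShotSet] = []
    phase_models: list[ShotPhaseModel] = []
    for v, img in enumerate(truth):
        if v < 2:
            pm = zero_phase
        else:
            pm = make_shot_phases(
                shape, scheme.n_shots, amplitude=phase_amplitude, seed=seed + 100 + v
            )
        shotsets.append(
            encode_acquisition(
                img,
                coils,
                pm,
                scheme,
                noise_sigma=sigma,
                seed=seed + 1000 + v,
                nav_window=nav_window,
                calibration_image=phantom.baseline,
            )
        )
        phase_models.append(pm)
    return DiffusionFixture(
        phantom=phantom,
        coils=coils,
        scheme=scheme,
        shotsets=shotsets,
        phase_models=phase_models,
        truth_images=truth,
        noise_sigma=sigma,
        seed=seed,
    )
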