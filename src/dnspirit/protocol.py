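"""EPI timing, point-spread-function, displacement, and SNR simulation.

Deterministic desk-scale models for in-plane segmented (multi-shot)
spin-echo diffusion EPI, as used in 3D multi-slab acquisitions.  The
models quantify the protocol trade-offs that motivate segmentation at
submillimeter resolution:

* echo spacing and its reduction by the segmentation factor ``n_seg``,
  which governs off-resonance image displacement;
* T2/T2' signal modulation across the echo train, which broadens the
  phase-encode point-spread function (T2* blurring) and sets the
  effective resolution;
* minimum echo time under a Stejskal-Tanner pulsed-gradient diffusion
  preparation, which sets the T2 signal penalty;
* a relative SNR model combining field strength, voxel volume, sampling
  duration, and relaxation.

The readout model is ramp-sampled trapezoidal EPI: the ADC window per
line lasts ``1 / bw_pixel`` and extends halfway into the adjacent
gradient ramps, so the echo spacing is ``1/bw_pixel + t_ramp`` with
``t_ramp = G_read / slew``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .fourier import ifft1c, center_pad

GAMMA_BAR = 42.577478518e6  # gyromagnetic ratio of 1H, Hz/T
GAMMA = 2.0 * np.pi * GAMMA_BAR  # rad/s/T


class InvalidParameterError(ValueError):
    """A protocol/hardware/tissue parameter is out of its valid domain."""


class InfeasibleProtocolError(ValueError):
    """The requested protocol cannot be realized (timing/gradient limits)."""


class DegeneratePsfError(ValueError):
    """The PSF has no usable half-maximum crossings."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HardwareSpec:
    """Scanner hardware: field strength and gradient system.

    Parameters
    ----------
    B0 : field strength in tesla.
    Gmax : maximum gradient amplitude in mT/m (diffusion encoding).
    slew : gradient slew rate in T/m/s (readout ramps).
    t_exc, t_ref : excitation / refocusing RF durations in ms.
    """

    B0: float = 3.0
    Gmax: float = 80.0
    slew: float = 200.0
    t_exc: float = 6.0
    t_ref: float = 10.0

    def __post_init__(self) -> None:
        for name in ("B0", "Gmax", "slew", "t_exc", "t_ref"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


@dataclass(frozen=True)
class TissueRelaxation:
    """Tissue relaxation times in ms; T2' is derived, never stored.

    White-matter defaults: 832/79.6/53.2 ms at 3T; use
    :meth:`wm_7t` for the 1220/47/26.8 ms values at 7T.
    """

    T1: float = 832.0
    T2: float = 79.6
    T2star: float = 53.2

    def __post_init__(self) -> None:
        if not (0 < self.T2star <= self.T2 <= self.T1):
            raise InvalidParameterError("require 0 < T2* <= T2 <= T1")

    @property
    def T2prime(self) -> float:
        """Reversible-dephasing time: 1/T2' = 1/T2* - 1/T2 (ms)."""
        inv = 1.0 / self.T2star - 1.0 / self.T2
        return np.inf if inv == 0 else 1.0 / inv

    @classmethod
    def wm_3t(cls) -> "TissueRelaxation":
        return cls(832.0, 79.6, 53.2)

    @classmethod
    def wm_7t(cls) -> "TissueRelaxation":
        return cls(1220.0, 47.0, 26.8)


@dataclass(frozen=True)
class SequenceProtocol:
    """Acquisition protocol parameters.

    ``pf`` is the partial-Fourier fraction of acquired ky lines
    (early lines skipped); ``pf_mode`` selects how the missing band is
    treated in the PSF simulation (``"zp"`` zero fill, ``"cs"``
    conjugate-symmetric fill, ``"none"`` == full sampling).
    """

    fov_x: float = 220.0
    fov_y: float = 220.0
    fov_z: float = 120.0
    res: float = 0.6
    n_seg: int = 1
    n_acq: int | None = None
    pf: float = 1.0
    pf_mode: str = "none"
    bw_pixel: float = 992.0
    tr: float = 2500.0
    b_value: float = 1000.0

    def __post_init__(self) -> None:
        if self.res <= 0:
            raise InvalidParameterError("resolution must be > 0")
        if min(self.fov_x, self.fov_y, self.fov_z) <= 0:
            raise InvalidParameterError("FOV must be > 0")
        if self.n_seg < 1:
            raise InvalidParameterError("n_seg must be >= 1")
        n_acq = self.n_seg if self.n_acq is None else self.n_acq
        if not (1 <= n_acq <= self.n_seg):
            raise InvalidParameterError("require 1 <= n_acq <= n_seg")
        if not (0.5 < self.pf <= 1.0):
            raise InvalidParameterError("partial-Fourier fraction must be in (0.5, 1]")
        if self.pf_mode not in ("none", "zp", "cs"):
            raise InvalidParameterError("pf_mode must be none/zp/cs")
        if self.bw_pixel <= 0 or self.tr <= 0:
            raise InvalidParameterError("bw_pixel and tr must be > 0")
        if self.b_value < 0:
            raise InvalidParameterError("b_value must be >= 0")

    @property
    def effective_acceleration(self) -> float:
        n_acq = self.n_seg if self.n_acq is None else self.n_acq
        return self.n_seg / n_acq


@dataclass(frozen=True)
class EpiTiming:
    """Derived timing of a segmented EPI readout (all times in ms)."""

    n_pe: int
    n_par: int
    n_x: int
    es: float
    es_eff: float  # es / n_seg; stored so es == es_eff * n_seg exactly
    lines_per_shot: int
    t_center: float
    te: float
    delta: float
    Delta: float
    readout_dur: float
    n_seg: int


@dataclass(frozen=True)
class PsfProfile:
    """Phase-encode signal modulation and its point-spread function."""

    modulation: np.ndarray  # complex weight per ky line, length n_pe
    psf: np.ndarray  # complex PSF on the upsampled grid
    psf_ideal: np.ndarray  # |PSF| of flat, fully sampled modulation, same grid
    pad: int  # upsampling factor of the PSF grid
    res: float  # nominal voxel size, mm


@dataclass(frozen=True)
class FwhmResult:
    """Effective-resolution summary of a PSF.

    ``blurring_frac`` is (effective - nominal)/nominal with the
    effective resolution taken as the PSF FWHM in voxel units times the
    nominal voxel size.  ``blurring_vs_ideal`` instead normalizes by the
    FWHM of the ideal (no-decay, fully sampled) PSF of the same grid, so
    it is exactly zero for an ideal acquisition.
    """

    fwhm_voxels: float
    eff_res_mm: float
    blurring_frac: float
    blurring_vs_ideal: float


@dataclass(frozen=True)
class SnrEstimate:
    """Relative SNR and its multiplicative factor breakdown."""

    rel_snr: float
    factors: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _round_to_multiple(x: float, m: int) -> int:
    return int(round(x / m)) * m


def derive_matrix(protocol: SequenceProtocol) -> tuple[int, int, int]:
    """Matrix size (n_pe, n_x, n_par) from FOV and nominal resolution.

    In-plane dimensions are rounded to the nearest multiple of ``n_seg``
    so that every segment acquires the same number of lines.
    """
    if protocol.res <= 0:
        raise InvalidParameterError("resolution must be > 0")
    n_pe = _round_to_multiple(protocol.fov_y / protocol.res, protocol.n_seg)
    n_x = _round_to_multiple(protocol.fov_x / protocol.res, protocol.n_seg)
    n_par = int(round(protocol.fov_z / protocol.res))
    if min(n_pe, n_x, n_par) < 1:
        raise InvalidParameterError("degenerate matrix size")
    return n_pe, n_x, n_par


def solve_diffusion_timing(
    protocol: SequenceProtocol, hardware: HardwareSpec, gap: float = 1.0
) -> tuple[float, float]:
    """Smallest Stejskal-Tanner (delta, Delta) reaching the target b-value.

    Monopolar pulsed gradients at amplitude ``Gmax`` straddling the
    refocusing pulse: ``Delta = delta + t_ref + 2*gap`` (ms).  Solves
    ``b = gamma^2 G^2 delta^2 (Delta - delta/3)`` for delta by bisection
    (b is strictly increasing in delta).
    """
    if protocol.b_value == 0:
        return 0.0, 0.0
    g = hardware.Gmax * 1e-3  # T/m
    sep = (hardware.t_ref + 2.0 * gap) * 1e-3  # s

    def b_of(delta_s: float) -> float:
        return GAMMA**2 * g**2 * delta_s**2 * (delta_s + sep - delta_s / 3.0)

    target = protocol.b_value * 1e6  # s/mm^2 -> s/m^2
    lo, hi = 0.0, 1e-3
    while b_of(hi) < target:
        hi *= 2.0
        if hi > 1.0:
            raise InfeasibleProtocolError("b-value unreachable at Gmax")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if b_of(mid) < target:
            lo = mid
        else:
            hi = mid
    delta = 0.5 * (lo + hi) * 1e3  # ms
    return delta, delta + hardware.t_ref + 2.0 * gap


def compute_epi_timing(
    protocol: SequenceProtocol,
    hardware: HardwareSpec,
    tissue: TissueRelaxation | None = None,
    gap: float = 1.0,
) -> EpiTiming:
    """Full timing of a segmented spin-echo diffusion EPI readout.

    Echo spacing follows the ramp-sampled trapezoid model
    ``es = 1/bw_pixel + G_read/slew``; the echo time is the smallest TE
    accommodating both the excitation-to-refocusing half (RF + first
    diffusion lobe) and the refocusing-to-echo half (second lobe + EPI
    train up to the k-space center line).
    """
    n_pe, n_x, n_par = derive_matrix(protocol)
    # readout gradient from pixel bandwidth: bw = gammabar * G * dx
    g_read = protocol.bw_pixel / (GAMMA_BAR * protocol.res * 1e-3)  # T/m
    if g_read > hardware.Gmax * 1e-3:
        raise InfeasibleProtocolError("readout gradient exceeds Gmax")
    t_ramp = g_read / hardware.slew * 1e3  # ms
    es_eff = (1.0 / protocol.bw_pixel * 1e3 + t_ramp) / protocol.n_seg
    es = es_eff * protocol.n_seg  # ms; representable as es_eff * n_seg
    lines_per_shot = int(np.ceil(protocol.pf * n_pe / protocol.n_seg))
    t_center = (protocol.pf - 0.5) * n_pe / protocol.n_seg * es
    delta, Delta = solve_diffusion_timing(protocol, hardware, gap=gap)
    pre = hardware.t_exc / 2.0 + gap + delta + gap + hardware.t_ref / 2.0
    post = hardware.t_ref / 2.0 + gap + delta + gap + t_center
    te = 2.0 * max(pre, post)
    if te > protocol.tr:
        raise InfeasibleProtocolError(f"TE {te:.1f} ms exceeds TR {protocol.tr} ms")
    return EpiTiming(
        n_pe=n_pe,
        n_par=n_par,
        n_x=n_x,
        es=es,
        es_eff=es_eff,
        lines_per_shot=lines_per_shot,
        t_center=t_center,
        te=te,
        delta=delta,
        Delta=Delta,
        readout_dur=lines_per_shot * es,
        n_seg=protocol.n_seg,
    )


def _line_times(timing: EpiTiming, protocol: SequenceProtocol) -> np.ndarray:
    """Acquisition time (ms, absolute) of each ky line on the full grid.

    Interleaved segmentation: line ``l`` is the ``floor(l/n_seg)``-th
    echo of its shot; all shots share the same echo-train timing, so the
    combined k-space carries a staircase time profile with step ``es``
    every ``n_seg`` lines.  The spin echo coincides with the k-space
    center line ``n_pe // 2``.
    """
    n_pe = timing.n_pe
    l = np.arange(n_pe)
    j = np.floor(l / protocol.n_seg)
    j_center = np.floor((n_pe // 2) / protocol.n_seg)
    return timing.te + (j - j_center) * timing.es


def simulate_psf(
    timing: EpiTiming,
    tissue: TissueRelaxation,
    protocol: SequenceProtocol,
    pad: int = 16,
) -> PsfProfile:
    """Phase-encode PSF under spin-echo T2/T2' signal modulation.

    Each ky line is weighted ``exp(-(t-TE)/T2) * exp(-|t-TE|/T2')``
    relative to the echo (the T2 factor of the center line itself,
    ``exp(-TE/T2)``, scales the whole modulation and not the PSF shape;
    it is included so the center-line weight equals the spin-echo
    amplitude).  Partial Fourier removes the early band and either
    leaves it zero (``zp``) or fills it with conjugate-symmetric values
    (``cs``, assuming a real image).  The PSF is the zero-padded
    centered inverse DFT of the modulation.
    """
    n_pe = timing.n_pe
    t = _line_times(timing, protocol)
    dt = t - timing.te
    t2p = tissue.T2prime
    mod = np.exp(-t / tissue.T2) * np.exp(-np.abs(dt) / t2p)
    mod = mod.astype(complex)
    if protocol.pf < 1.0 and protocol.pf_mode != "none":
        first = n_pe - int(np.ceil(protocol.pf * n_pe))
        acquired = np.zeros(n_pe, dtype=bool)
        acquired[first:] = True
        mod_pf = np.where(acquired, mod, 0.0 + 0.0j)
        if protocol.pf_mode == "cs":
            # centered grid (DC at n//2): line l mirrors line (n - l) mod n
            mirror = (n_pe - np.arange(n_pe)) % n_pe
            fill = np.conj(mod_pf[mirror])
            mod = np.where(acquired, mod_pf, fill)
        else:
            mod = mod_pf

    def _psf(m: np.ndarray) -> np.ndarray:
        padded = center_pad(m, (n_pe * pad,))
        # orthonormal 1D transform; scale irrelevant for FWHM
        return ifft1c(padded)

    psf = _psf(mod)
    psf_ideal = np.abs(_psf(np.ones(n_pe, dtype=complex)))
    return PsfProfile(modulation=mod, psf=psf, psf_ideal=psf_ideal, pad=pad, res=protocol.res)


def _fwhm_samples(mag: np.ndarray) -> float:
    """FWHM of a sampled unimodal profile by linear interpolation."""
    i = int(np.argmax(mag))
    half = mag[i] / 2.0
    left = i
    while left > 0 and mag[left - 1] >= half:
        left -= 1
    right = i
    n = len(mag)
    while right < n - 1 and mag[right + 1] >= half:
        right += 1
    if left == 0 or right == n - 1:
        raise DegeneratePsfError("no half-maximum crossing on the PSF grid")
    xl = left - (mag[left] - half) / (mag[left] - mag[left - 1])
    xr = right + (mag[right] - half) / (mag[right] - mag[right + 1])
    return xr - xl


def measure_fwhm(profile: PsfProfile) -> FwhmResult:
    """Effective resolution and blurring fractions from a PSF.

    The effective resolution is the FWHM of |PSF| expressed in nominal
    voxels times the nominal voxel size; ``blurring_vs_ideal``
    additionally normalizes by the ideal same-grid PSF FWHM (Dirichlet
    kernel, ~1.21 voxels) so a decay-free acquisition scores 0.
    """
    mag = np.abs(profile.psf)
    fwhm_vox = _fwhm_samples(mag) / profile.pad
    fwhm_ideal = _fwhm_samples(profile.psf_ideal) / profile.pad
    eff_res = profile.res * fwhm_vox
    return FwhmResult(
        fwhm_voxels=fwhm_vox,
        eff_res_mm=eff_res,
        blurring_frac=fwhm_vox - 1.0,
        blurring_vs_ideal=fwhm_vox / fwhm_ideal - 1.0,
    )


def compute_snr(
    protocol: SequenceProtocol,
    timing: EpiTiming,
    tissue: TissueRelaxation,
    hardware: HardwareSpec,
    eff_res_mm: float | None = None,
) -> SnrEstimate:
    """Relative SNR model for an unaccelerated segmented acquisition.

    ``rel_snr = B0^1.65 * dx * dy_eff * dz * sqrt(n_pe*n_par/bw)
    * exp(-TE/T2) * (1 - exp(-TR/T1))``, with the phase-encode voxel
    size taken from the PSF FWHM and the readout/partition sizes at
    nominal resolution.  Unitless; meaningful only as a ratio between
    protocols.
    """
    if eff_res_mm is None:
        eff_res_mm = protocol.res
    if eff_res_mm <= 0:
        raise InvalidParameterError("effective resolution must be > 0")
    f_field = hardware.B0**1.65
    f_voxel = protocol.res * eff_res_mm * protocol.res
    f_sampling = np.sqrt(timing.n_pe * timing.n_par / protocol.bw_pixel)
    f_relax = np.exp(-timing.te / tissue.T2) * (1.0 - np.exp(-protocol.tr / tissue.T1))
    rel = f_field * f_voxel * f_sampling * f_relax
    return SnrEstimate(
        rel_snr=rel,
        factors={
            "field": f_field,
            "voxel": f_voxel,
            "sampling": f_sampling,
            "relaxation": f_relax,
        },
    )


def compute_displacement(
    delta_f: float, timing: EpiTiming, protocol: SequenceProtocol
) -> float:
    """Off-resonance image displacement along phase encoding, in mm.

    A constant offset ``delta_f`` (Hz) shifts the image by
    ``delta_f * es_eff * n_pe`` pixels (phase accrual of one cycle over
    the effective readout), times the voxel size.
    """
    return delta_f * timing.es_eff * 1e-3 * timing.n_pe * protocol.res


def simulate_protocol(
    protocol: SequenceProtocol,
    hardware: HardwareSpec,
    tissue: TissueRelaxation,
    delta_f: float = 50.0,
) -> dict:
    """Run the full chain for one protocol; returns a flat result row."""
    timing = compute_epi_timing(protocol, hardware)
    prof = simulate_psf(timing, tissue, protocol)
    fw = measure_fwhm(prof)
    snr = compute_snr(protocol, timing, tissue, hardware, eff_res_mm=fw.eff_res_mm)
    return {
        "res": protocol.res,
        "n_seg": protocol.n_seg,
        "pf": protocol.pf,
        "pf_mode": protocol.pf_mode,
        "B0": hardware.B0,
        "n_pe": timing.n_pe,
        "es": timing.es,
        "es_eff": timing.es_eff,
        "te": timing.te,
        "eff_res_mm": fw.eff_res_mm,
        "fwhm_voxels": fw.fwhm_voxels,
        "blurring_frac": fw.blurring_frac,
        "blurring_vs_ideal": fw.blurring_vs_ideal,
        "rel_snr": snr.rel_snr,
        "displacement_mm": compute_displacement(delta_f, timing, protocol),
        "t2_decay": float(np.exp(-timing.te / tissue.T2)),
        "feasible": True,
    }


def sweep_protocols(
    protocols: Iterable[SequenceProtocol],
    hardware: HardwareSpec,
    tissue: TissueRelaxation,
    delta_f: float = 50.0,
) -> list[dict]:
    """Evaluate a grid of protocols; infeasible points are flagged in-row."""
    rows: list[dict] = []
    protocols = list(protocols)
    if not protocols:
        raise InvalidParameterError("empty protocol grid")
    for p in protocols:
        try:
            rows.append(simulate_protocol(p, hardware, tissue, delta_f=delta_f))
        except (InfeasibleProtocolError, DegeneratePsfError) as exc:
            rows.append(
                {
                    "res": p.res,
                    "n_seg": p.n_seg,
                    "pf": p.pf,
                    "pf_mode": p.pf_mode,
                    "B0": hardware.B0,
                    "feasible": False,
                    "error": str(exc),
                }
            )
    return rows
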