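"""Shared fixtures: the reference synthetic study is reconstructed once
per session and reused by every test that inspects its results."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import dnspirit as dn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


FIXTURE_SHAPE = (128, 128)
RECON_CFG = dict(cg_tol=1e-5, cg_max_iter=50, n_outer=3)


@pytest.fixture(scope="session")
def reference_fixture() -> dn.DiffusionFixture:
    """128^2, 8 coils, 6 shots, SNR 5, seed 7: two b=0 repeats + 6 DWIs."""
    return dn.make_diffusion_fixture(
        shape=FIXTURE_SHAPE, n_coils=8, n_seg=6, snr=5.0, seed=7, n_directions=6
    )


@pytest.fixture(scope="session")
def reference_calibration(reference_fixture):
    calib = reference_fixture.shotsets[0].calibration
    kernel = dn.calibrate_spirit_kernel(calib)
    sens = dn.estimate_sensitivities(calib, FIXTURE_SHAPE).sens
    return kernel, sens


@pytest.fixture(scope="session")
def reference_study(reference_fixture, reference_calibration):
    """All volumes reconstructed with SPIRiT, SPIRiT + standalone
    denoising, and DnSPIRiT; magnitude images plus per-method noise
    sigma from the two b=0 repeats."""
    fx = reference_fixture
    kernel, sens = reference_calibration
    cfg = dn.ReconConfig(**RECON_CFG)
    out = {"spirit": [], "spirit+denoise": [], "dnspirit": []}
    for ss in fx.shotsets:
        pm = dn.estimate_phase_maps(ss.navigators, FIXTURE_SHAPE)
        r_sp = dn.spirit_recon(ss, pm, kernel, cfg)
        out["spirit"].append(np.abs(r_sp.image))
        out["spirit+denoise"].append(np.abs(dn.apply_denoiser("llr_magnitude", r_sp.image)))
        out["dnspirit"].append(np.abs(dn.dnspirit_recon(ss, pm, kernel, sens, cfg).image))
    mask = fx.phantom.brain_mask
    sigmas = {
        name: dn.noise_std_from_repeats(imgs[0], imgs[1], mask)
        for name, imgs in out.items()
    }
    return {"images": out, "sigmas": sigmas}


@pytest.fixture(scope="session")
def undersample_study(reference_fixture, reference_calibration):
    """One DWI volume reconstructed at R_eff = 1, 2, 3 (6, 3, 2 of the
    6 segments kept) with both methods."""
    fx = reference_fixture
    kernel, sens = reference_calibration
    cfg = dn.ReconConfig(**RECON_CFG)
    ss = fx.shotsets[2]
    results = {}
    for n_keep in (6, 3, 2):
        sub = dn.retrospective_undersample(ss, n_keep)
        pm = dn.estimate_phase_maps(sub.navigators, FIXTURE_SHAPE)
        results[sub.scheme.r_eff] = {
            "spirit": np.abs(dn.spirit_recon(sub, pm, kernel, cfg).image),
            "dnspirit": np.abs(dn.dnspirit_recon(sub, pm, kernel, sens, cfg).image),
        }
    return results


# ---------------------------------------------------------------------------
# shared helpers (imported by test modules)
# ---------------------------------------------------------------------------


def make_small_noiseless(shape=(64, 64), n_seg=4, phase_amplitude=1.5, seed=3,
                         n_coils=4, n_directions=1, **kw):
    """A small noiseless study for exactness-type tests."""
    return dn.make_diffusion_fixture(
        shape=shape,
        n_coils=n_coils,
        n_seg=n_seg,
        snr=np.inf,
        phase_amplitude=phase_amplitude,
        n_directions=n_directions,
        seed=seed,
        **kw,
    )


def make_tiny_system(n=16, n_coils=2, n_seg=2, seed=17, phase_amplitude=1.0):
    """A 16^2-scale encoded acquisition small enough for dense oracles.

    Returns (shotset, truth phase maps, noise-free image, coils).
    """
    rng = np.random.default_rng(seed)
    from dnspirit.synth import _bandlimited_field

    img = (
        _bandlimited_field((n, n), 6, rng) + 1j * _bandlimited_field((n, n), 6, rng)
    )
    coils = dn.make_sensitivities((n, n), n_coils=n_coils, seed=seed)
    phases = dn.make_shot_phases((n, n), n_seg, amplitude=phase_amplitude,
                                 seed=seed + 1, window=4)
    scheme = dn.make_sampling_scheme(n, n_seg)
    ss = dn.encode_acquisition(img, coils, phases, scheme, noise_sigma=0.0,
                               nav_window=12)
    return ss, truth_phase_maps(phases), img, coils


def truth_phase_maps(model: dn.ShotPhaseModel) -> dn.PhaseMaps:
    """Generator-truth shot phases referenced to shot 0."""
    rel = model.phases - model.phases[0]
    return dn.PhaseMaps(maps=np.exp(1j * rel))


def dense_normal_matrix(apply_normal, shape) -> np.ndarray:
    """Materialize a Hermitian operator by probing with basis vectors."""
    n = int(np.prod(shape))
    mat = np.zeros((n, n), dtype=complex)
    for j in range(n):
        e = np.zeros(n, dtype=complex)
        e[j] = 1.0
        mat[:, j] = apply_normal(e.reshape(shape)).ravel()
    return mat
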