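"""Reconstruction operator correctness and end-to-end properties."""

import numpy as np
import pytest

import dnspirit as dn
from dnspirit.fourier import fft2c, ifft2c
from dnspirit.recon import ShotSystem, _forward_shot, _adjoint_shot

from conftest import (
    dense_normal_matrix,
    make_small_noiseless,
    make_tiny_system,
    truth_phase_maps,
)


@pytest.fixture(scope="module")
def small_study():
    """Noiseless 64^2 study with motion phases: everything exactness-grade."""
    fx = make_small_noiseless()
    ss = fx.shotsets[2]
    kernel = dn.calibrate_spirit_kernel(ss.calibration)
    sens = dn.estimate_sensitivities(ss.calibration, (64, 64)).sens
    return fx, ss, kernel, sens


class TestPhaseEstimation:
    def test_noiseless_bandlimited_phase_recovered(self, small_study):
        fx, ss, *_ = small_study
        pm = dn.estimate_phase_maps(ss.navigators, (64, 64))
        true = truth_phase_maps(fx.phase_models[2])
        support = np.abs(fx.truth_images[2]) > 0.1 * np.abs(fx.truth_images[2]).max()
        err = np.angle(pm.maps * np.conj(true.maps))[:, support]
        assert np.sqrt(np.mean(err**2)) < 0.05

    def test_identical_navigators_give_zero_relative_phase(self, small_study):
        _, ss, *_ = small_study
        navs = np.repeat(ss.navigators[:1], ss.n_shots, axis=0)
        pm = dn.estimate_phase_maps(navs, (64, 64))
        assert np.allclose(pm.maps, 1.0, atol=1e-12)

    def test_hamming_window_reduces_noisy_phase_error(self):
        # 20 noise draws at SNR 10: smoothed estimator beats raw zero-padding
        fx0 = make_small_noiseless(seed=13)
        truth = truth_phase_maps(fx0.phase_models[2])
        img = fx0.truth_images[2]
        support = np.abs(img) > 0.1 * np.abs(img).max()
        sigma = np.mean(np.abs(img)[fx0.phantom.brain_mask]) / 10.0
        win_err, raw_err = [], []
        for draw in range(20):
            ss = dn.encode_acquisition(
                img, fx0.coils, fx0.phase_models[2], fx0.scheme,
                noise_sigma=sigma, seed=500 + draw,
            )
            pm = dn.estimate_phase_maps(ss.navigators, (64, 64))
            # naive estimator: no k-space taper
            from dnspirit.fourier import center_pad
            imgs = ifft2c(center_pad(ss.navigators, (64, 64)))
            naive = np.exp(1j * np.angle(np.sum(imgs * np.conj(imgs[0:1]), axis=1)))
            for est, log in ((pm.maps, win_err), (naive, raw_err)):
                e = np.angle(est * np.conj(truth.maps))[:, support]
                log.append(np.sqrt(np.mean(e**2)))
        assert np.mean(win_err) < np.mean(raw_err)

    def test_missing_navigators_rejected(self):
        with pytest.raises(dn.InvalidInputError):
            dn.estimate_phase_maps(None, (64, 64))


class TestOperators:
    def test_shot_forward_adjoint_identity(self, small_study):
        fx, ss, kernel, _ = small_study
        rng = np.random.default_rng(0)
        shape = ss.data.shape[1:]
        pmap = truth_phase_maps(fx.phase_models[2]).maps[1]
        mask = ss.masks[1]
        x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        y = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        lhs = np.vdot(y, _forward_shot(x, pmap, mask))
        rhs = np.vdot(_adjoint_shot(y, pmap, mask), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_normal_operator_hermitian_with_kernel_rows(self, small_study):
        fx, ss, kernel, _ = small_study
        pm = truth_phase_maps(fx.phase_models[2])
        system = ShotSystem(ss.data, ss.masks, pm, kernel, lambda1=1.3, lambda2=0.7)
        rng = np.random.default_rng(1)
        shape = ss.data.shape[1:]
        x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        y = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        lhs = np.vdot(y, system.normal(x))
        rhs = np.vdot(system.normal(y), x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_identity_system_returns_data(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((1, 2, 16, 16)) + 1j * rng.standard_normal((1, 2, 16, 16))
        masks = np.ones((1, 16), dtype=bool)
        pm = dn.PhaseMaps(maps=np.ones((1, 16, 16), dtype=complex))
        x, info = dn.cg_solve_normal(y, masks, pm, None, 0.0, cg_tol=1e-12)
        assert np.linalg.norm(x - y[0]) / np.linalg.norm(y) < 1e-8

    def test_cg_matches_dense_direct_solve(self):
        # 16x16 plane, 2 coils, 2 shots, kernel + prior rows: explicit-matrix oracle
        rng = np.random.default_rng(3)
        nc, n = 2, 16
        ss, pm, _, _ = make_tiny_system(n=n, n_coils=nc, seed=17)
        kernel = dn.calibrate_spirit_kernel(ss.calibration, kernel_size=3)
        z = rng.standard_normal((nc, n, n)) + 1j * rng.standard_normal((nc, n, n))
        lam1, lam2 = 0.5, 0.3
        system = ShotSystem(ss.data, ss.masks, pm, kernel, lam1, lam2)
        mat = dense_normal_matrix(system.normal, (nc, n, n))
        b = system.rhs(z)
        x_direct = np.linalg.solve(mat, b.ravel()).reshape(nc, n, n)
        x_cg, _ = dn.cg_solve_normal(
            ss.data, ss.masks, pm, kernel, lam1, lambda2=lam2, z_prev=z,
            cg_tol=1e-13, cg_max_iter=3000,
        )
        assert np.linalg.norm(x_cg - x_direct) / np.linalg.norm(x_direct) < 1e-8

    def test_cg_residual_log_non_increasing(self, small_study):
        fx, ss, kernel, _ = small_study
        pm = truth_phase_maps(fx.phase_models[2])
        _, info = dn.cg_solve_normal(
            ss.data, ss.masks, pm, kernel, 1.0, cg_tol=1e-10, cg_max_iter=50
        )
        res = np.array(info["residuals"])
        assert not info["diverged"]
        assert np.all(np.diff(res) <= 1e-12 + 0.05 * res[:-1])

    def test_non_finite_data_rejected(self, small_study):
        fx, ss, kernel, _ = small_study
        bad = ss.data.copy()
        bad[0, 0, 0, 0] = np.nan
        pm = truth_phase_maps(fx.phase_models[2])
        with pytest.raises(dn.InvalidInputError):
            dn.cg_solve_normal(bad, ss.masks, pm, kernel, 1.0)

    def test_all_zero_shots_reconstruct_to_zero(self, small_study):
        fx, ss, kernel, _ = small_study
        pm = truth_phase_maps(fx.phase_models[2])
        x, info = dn.cg_solve_normal(
            np.zeros_like(ss.data), ss.masks, pm, kernel, 1.0
        )
        assert np.all(x == 0.0) and info["iterations"] == 0


class TestSpirit:
    def test_noiseless_fully_sampled_data_reproduced(self, small_study):
        fx, ss, kernel, _ = small_study
        pm = truth_phase_maps(fx.phase_models[2])
        result = dn.spirit_recon(ss, pm, kernel, dn.ReconConfig(cg_tol=1e-9, cg_max_iter=200))
        pred = np.stack(
            [_forward_shot(result.kspace, pm.maps[i], ss.masks[i]) for i in range(ss.n_shots)]
        )
        assert np.linalg.norm(pred - ss.data) / np.linalg.norm(ss.data) < 0.01

    def test_phase_correction_with_truth_maps_is_amplitude_independent(self):
        # reconstruction error must not grow with motion-phase severity
        errs = []
        for amp in (0.0, 1.5, 3.0):
            fx = make_small_noiseless(phase_amplitude=amp, seed=23)
            ss = fx.shotsets[2]
            kernel = dn.calibrate_spirit_kernel(ss.calibration)
            pm = truth_phase_maps(fx.phase_models[2])
            r = dn.spirit_recon(ss, pm, kernel, dn.ReconConfig(cg_tol=1e-8, cg_max_iter=200))
            errs.append(
                dn.nrmse(np.abs(r.image), np.abs(fx.truth_images[2]), fx.phantom.brain_mask)
            )
        assert max(errs) - min(errs) < 0.01

    def test_undersampled_spirit_beats_zero_filling(self):
        fx = make_small_noiseless(n_seg=4, seed=29)
        ss = dn.retrospective_undersample(fx.shotsets[2], 2)  # R_eff = 2
        kernel = dn.calibrate_spirit_kernel(ss.calibration)
        pm = truth_phase_maps(fx.phase_models[2])
        pm = dn.PhaseMaps(maps=pm.maps[::2])
        r = dn.spirit_recon(ss, pm, kernel, dn.ReconConfig(cg_tol=1e-7, cg_max_iter=150))
        zf = dn.combine_coils(ifft2c(ss.data.sum(axis=0)), mode="sos")
        truth = np.abs(fx.truth_images[2])
        mask = fx.phantom.brain_mask
        assert dn.nrmse(np.abs(r.image), truth, mask) < dn.nrmse(zf, truth, mask)


class TestDnSpirit:
    def test_identity_denoiser_converges_to_spirit_fixed_point(self, small_study):
        fx, ss, kernel, sens = small_study
        pm = truth_phase_maps(fx.phase_models[2])
        cfg = dn.ReconConfig(
            cg_tol=1e-8, cg_max_iter=200, n_outer=5,
            denoiser="identity", recombination="complex_sense",
        )
        r_dn = dn.dnspirit_recon(ss, pm, kernel, sens, cfg)
        r_sp = dn.spirit_recon(ss, pm, kernel, cfg, sens=sens)
        diff = np.linalg.norm(r_dn.image - r_sp.image) / np.linalg.norm(r_sp.image)
        assert diff < 0.01

    def test_denoising_prior_reduces_error_on_noisy_data(self):
        fx = dn.make_diffusion_fixture((64, 64), n_coils=4, n_seg=4, snr=5, seed=31,
                                       n_directions=1)
        ss = fx.shotsets[2]
        kernel = dn.calibrate_spirit_kernel(ss.calibration)
        sens = dn.estimate_sensitivities(ss.calibration, (64, 64)).sens
        pm = dn.estimate_phase_maps(ss.navigators, (64, 64))
        cfg = dn.ReconConfig(cg_tol=1e-5, cg_max_iter=50, n_outer=3)
        r_sp = dn.spirit_recon(ss, pm, kernel, cfg)
        r_dn = dn.dnspirit_recon(ss, pm, kernel, sens, cfg)
        truth = np.abs(fx.truth_images[2])
        mask = fx.phantom.brain_mask
        assert dn.nrmse(np.abs(r_dn.image), truth, mask) < dn.nrmse(
            np.abs(r_sp.image), truth, mask
        )

    def test_objective_trace_logged_per_outer_iteration(self, small_study):
        fx, ss, kernel, sens = small_study
        pm = truth_phase_maps(fx.phase_models[2])
        cfg = dn.ReconConfig(cg_tol=1e-6, cg_max_iter=60, n_outer=3)
        r = dn.dnspirit_recon(ss, pm, kernel, sens, cfg)
        assert len(r.diagnostics["objective"]) == 3
        assert all(np.isfinite(v) for v in r.diagnostics["objective"])

    def test_unknown_denoiser_rejected(self, small_study):
        fx, ss, kernel, sens = small_study
        pm = truth_phase_maps(fx.phase_models[2])
        with pytest.raises(dn.UnknownDenoiserError):
            dn.dnspirit_recon(ss, pm, kernel, sens, dn.ReconConfig(denoiser="nope"))

    def test_deterministic_given_fixture_and_config(self, small_study):
        fx, ss, kernel, sens = small_study
        pm = truth_phase_maps(fx.phase_models[2])
        cfg = dn.ReconConfig(cg_tol=1e-6, cg_max_iter=40, n_outer=2)
        a = dn.dnspirit_recon(ss, pm, kernel, sens, cfg)
        b = dn.dnspirit_recon(ss, pm, kernel, sens, cfg)
        assert np.array_equal(a.image, b.image)


class TestPartialFourier:
    def test_full_fraction_is_identity(self):
        rng = np.random.default_rng(4)
        k = rng.standard_normal((2, 32, 32)) + 1j * rng.standard_normal((2, 32, 32))
        assert np.array_equal(dn.partial_fourier_fill(k, 1.0, "zp"), k)

    def test_real_image_recovered_exactly_by_conjugate_symmetry(self):
        img = np.abs(dn.make_phantom((64, 64), seed=8).baseline)  # real image
        k = fft2c(img.astype(complex))
        filled = dn.partial_fourier_fill(k, 0.75, "cs")
        assert np.linalg.norm(filled - k) / np.linalg.norm(k) < 1e-10

    def test_zero_padding_blurs_more_than_conjugate_symmetry(self):
        img = np.abs(dn.make_phantom((64, 64), seed=8).baseline)
        k = fft2c(img.astype(complex))
        err_zp = np.linalg.norm(dn.partial_fourier_fill(k, 0.75, "zp") - k)
        err_cs = np.linalg.norm(dn.partial_fourier_fill(k, 0.75, "cs") - k)
        assert err_cs < err_zp

    def test_invalid_fraction_rejected(self):
        k = np.zeros((2, 16, 16), dtype=complex)
        with pytest.raises(dn.InvalidInputError):
            dn.partial_fourier_fill(k, 0.5, "zp")


class TestRetrospectiveUndersampling:
    def test_keep_all_is_identity(self, small_study):
        _, ss, *_ = small_study
        sub = dn.retrospective_undersample(ss, ss.n_shots)
        assert np.array_equal(sub.data, ss.data)
        assert sub.scheme.r_eff == 1.0

    @pytest.mark.parametrize("n_keep, r_eff", [(3, 2.0), (2, 3.0)])
    def test_effective_acceleration(self, n_keep, r_eff):
        # plane size divisible by n_seg so every segment has equal line count
        fx = make_small_noiseless(shape=(96, 96), n_seg=6, seed=2)
        sub = dn.retrospective_undersample(fx.shotsets[0], n_keep)
        assert sub.scheme.r_eff == r_eff
        full_count = fx.shotsets[0].masks.sum()
        assert sub.masks.sum() * fx.scheme.n_shots == full_count * n_keep

    def test_uneven_selection_rejected(self, small_study):
        _, ss, *_ = small_study
        with pytest.raises(dn.InvalidInputError):
            dn.retrospective_undersample(ss, 3)  # 4 shots not divisible by 3


class TestCoilCombination:
    def test_single_unit_coil(self):
        img = (np.ones((1, 8, 8)) * (1 + 1j)).astype(complex)
        sens = np.ones((1, 8, 8), dtype=complex)
        assert np.allclose(dn.combine_coils(img, sens, "sense"), img[0])
        assert np.allclose(dn.combine_coils(img, mode="sos"), np.abs(img[0]))

    def test_sense_mode_inverts_sensitivity_weighting(self):
        rng = np.random.default_rng(5)
        sens = dn.make_sensitivities((32, 32), n_coils=4, seed=5).sens
        img = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        combined = dn.combine_coils(sens * img[None], sens, "sense")
        support = np.sum(np.abs(sens) ** 2, axis=0) > 0.5
        assert np.linalg.norm((combined - img)[support]) / np.linalg.norm(img[support]) < 1e-10

    def test_sos_nonnegative(self):
        rng = np.random.default_rng(6)
        img = rng.standard_normal((3, 8, 8)) + 1j * rng.standard_normal((3, 8, 8))
        assert np.all(dn.combine_coils(img, mode="sos") >= 0.0)

    def test_zero_sensitivities_rejected_for_sense(self):
        img = np.ones((2, 8, 8), dtype=complex)
        with pytest.raises(dn.InvalidInputError):
            dn.combine_coils(img, np.zeros((2, 8, 8), complex), "sense")
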