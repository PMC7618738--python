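# dnspirit

Protocol simulation and denoiser-regularized reconstruction for
in-plane segmented 3D multi-slab diffusion MRI — on synthetic data,
desk scale, fully seeded.

Submillimeter diffusion MRI is SNR-starved: encoding a large EPI
matrix stretches the echo spacing, readout, and echo time, which
inflates off-resonance distortion, T2\* blurring, and T2 signal loss.
Splitting the ky lines into `N_seg` interleaved shots divides the
effective echo spacing and shortens TE — at the price of a multi-shot
reconstruction that must undo per-shot motion-induced phase errors.
This package is for researchers who want to (a) quantify those
protocol trade-offs with a transparent simulator and (b) experiment
with the reconstruction side: multi-shot SPIRiT with navigator-based
phase correction, regularized by a plug-and-play denoiser prior
("DnSPIRiT").

## The models

**Simulator.** Ramp-sampled EPI timing (`ES = 1/BW + G_read/slew`,
`ES_eff = ES/N_seg`), Stejskal–Tanner diffusion preparation
(`b = γ²G²δ²(Δ − δ/3)`), minimum spin-echo TE, and the phase-encode
point-spread function under the spin-echo envelope
`exp(−t/T2)·exp(−|t−TE|/T2′)`. Effective resolution is the PSF FWHM;
relative SNR follows

```
SNR ∝ B0^1.65 · Δx Δy_eff Δz · √(N_PE N_par / BW) · e^(−TE/T2) (1 − e^(−TR/T1)).
```

**Reconstruction.** For shots `y_i` with sampling masks `D_i` and
shot phases `P_i`, the multi-coil k-space `x` minimizes

```
Σ_i ‖D_i F P_i F⁻¹ x − y_i‖² + λ₁‖(G − I)x‖² + λ₂‖F⁻¹x − Φ(F⁻¹x)‖²
```

where `G` is a 5×5 SPIRiT self-consistency kernel calibrated on a
fully sampled central region and `Φ` is a black-box denoiser. The
plug-and-play splitting alternates a conjugate-gradient solve (with
`z = Φ(·)` held fixed) and a denoising step; iteration 1 is plain
phase-corrected SPIRiT. A locally-low-rank denoiser with a
Marchenko–Pastur threshold is built in; others attach via a registry.

A seeded synthetic layer (brain-like tensor phantom, smooth coil
maps, per-shot smooth phase errors, interleaved/partial-Fourier
sampling, navigators, calibration scan, complex Gaussian noise) makes
every stage testable without any data download. See
`docs/methods.md` for model details and limitations.

## Worked example

Simulate the trade-off that motivates segmentation — 0.6 mm vs 1 mm
EPI at 3T with 3 segments, no partial Fourier, 50 Hz off-resonance:

```
$ dnspirit reproduce sec4_numbers --outdir results
```

From `results/sec4_numbers.csv` (columns abridged):

| res (mm) | ES_eff (ms) | TE (ms) | displacement (mm) | blurring | e^(−TE/T2) |
|---------:|------------:|--------:|------------------:|---------:|-----------:|
| 0.6      | 0.401       | 182.0   | 4.40              | 42.0%    | 10.2%      |
| 1.0      | 0.295       | 100.0   | 3.23              | 27.1%    | 28.5%      |

Reading: at 0.6 mm with only 3 segments, a 50 Hz B0 offset displaces
the image by 4.4 mm (seven voxels), T2\* decay across the long echo
train broadens the voxel by ~42%, and only ~10% of the signal
survives to the echo — submillimeter imaging needs a higher `N_seg`.

Reconstruction under retrospective shot under-sampling (keeping 3 and
2 of 6 segments, i.e. R_eff = 2 and 3) on the seeded noisy phantom:

```
$ dnspirit reproduce fig3_undersampling --outdir results --seed 7 --size 64
{"R2": {"spirit_nrmse": 0.3703, "dnspirit_nrmse": 0.2625},
 "R3": {"spirit_nrmse": 0.8522, "dnspirit_nrmse": 0.6846}}
```

NRMSE is measured against each method's own fully sampled
reconstruction: errors grow with acceleration for both methods, and
the denoiser prior consistently reduces them.

Library use mirrors the CLI:

```python
import dnspirit as dn

fx = dn.make_diffusion_fixture(shape=(128, 128), n_coils=8, n_seg=6, snr=5, seed=7)
ss = fx.shotsets[2]                       # first DWI volume
kernel = dn.calibrate_spirit_kernel(ss.calibration)
sens = dn.estimate_sensitivities(ss.calibration, (128, 128)).sens
pm = dn.estimate_phase_maps(ss.navigators, (128, 128))
result = dn.dnspirit_recon(ss, pm, kernel, sens, dn.ReconConfig(n_outer=3))
print(dn.nrmse(abs(result.image), abs(fx.truth_images[2]), fx.phantom.brain_mask))
```

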