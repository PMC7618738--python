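# Methods

This package has two halves that meet in the middle: a deterministic
simulator for in-plane segmented spin-echo diffusion EPI protocols
(timing, point-spread function, off-resonance displacement, relative
SNR), and a multi-shot parallel-imaging reconstruction with a
plug-and-play denoiser prior (DnSPIRiT), exercised end to end on
seeded synthetic multi-coil k-space. This note records the models,
their assumptions, the defaults, and the deliberate simplifications.

## Protocol simulation

### Readout timing

The EPI readout is modelled as a ramp-sampled trapezoidal gradient
train. The readout gradient amplitude follows from the receiver
bandwidth per pixel, `G_read = BW / (gammabar * dx)`, and the ramp
time from the slew rate, `t_ramp = G_read / slew` (default slew
200 T/m/s, configurable in `HardwareSpec`). Because the ADC window of
one line (`1/BW`) extends halfway into the adjacent ramps, consecutive
lines are separated by

```
ES = 1/BW + t_ramp .
```

Interleaved segmentation with `N_seg` in-plane segments leaves the
per-shot echo spacing unchanged but spaces consecutive ky lines of the
*combined* k-space by `ES_eff = ES / N_seg`, which governs
off-resonance distortion. `ES_eff` is the stored primitive and
`ES = ES_eff * N_seg` holds exactly in floating point.

Matrix sizes are the FOV over the nominal resolution rounded to the
nearest multiple of `N_seg` in-plane (so each segment acquires the
same number of lines) and to the nearest integer through-plane. The
through-plane count ignores slab partitioning/oversampling of real
multi-slab protocols; only the in-plane sizes are validated.

### Diffusion preparation and echo time

Diffusion encoding uses the Stejskal-Tanner pulsed-gradient model with
monopolar lobes of duration `delta` at `G_max` straddling the
refocusing pulse, `Delta = delta + t_ref + 2 * gap` with fixed 1 ms
safety gaps. `delta` is the smallest root of
`b = gamma^2 G^2 delta^2 (Delta - delta/3)` (bisection on the
monotone curve). The echo time is the smallest TE accommodating both
spin-echo halves:

```
TE = 2 * max( t_exc/2 + gap + delta + gap + t_ref/2 ,
              t_ref/2  + gap + delta + gap + t_center )
```

with `t_center = (pf - 0.5) * N_pe / N_seg * ES` the time from the
start of the echo train to the k-space center line. With the default
hardware (80 mT/m, 6/10 ms RF pulses) this reproduces the tabulated
minimum TE of a fully sampled 0.65 mm 3T protocol to within 1 ms.

### Point-spread function and effective resolution

Each ky line acquired at time `t` (staircase profile: one step of `ES`
per group of `N_seg` lines, spin echo at the center line) is weighted
by the spin-echo envelope

```
m(t) = exp(-t/T2) * exp(-|t - TE| / T2')   with  1/T2' = 1/T2* - 1/T2 .
```

Signal therefore *rises* toward the echo at rate `1/T2 - 1/T2'` and
decays afterwards at `1/T2*`. Partial Fourier removes the early-ky
band; the missing band is zero-filled (`zp`) or filled with
conjugate-symmetric values assuming a real object (`cs`). The PSF is
the centered inverse DFT of the modulation, zero-padded 16x for
sub-voxel FWHM interpolation accuracy.

Two blurring figures are reported:

* `blurring_frac = FWHM_voxels - 1`: effective resolution is the PSF
  FWHM in voxel units times the nominal voxel size. This is the
  figure quoted in the package's headline numbers, and it also makes
  the fully sampled 0.65 mm / `N_seg`=6 protocol come out at ~0.85 mm
  effective.
* `blurring_vs_ideal = FWHM / FWHM_ideal - 1`: normalized by the
  no-decay, fully sampled PSF of the same grid (a Dirichlet kernel,
  FWHM ~1.207 voxels). This is exactly zero for an ideal acquisition
  and is the quantity used in the "no relaxation, no blurring"
  invariant tests.

Both are monotone in the same direction across every sweep used here,
so trend statements are insensitive to the choice.

### Relative SNR

```
SNR ∝ B0^1.65 * dx * dy_eff * dz * sqrt(N_pe * N_par / BW)
      * exp(-TE/T2) * (1 - exp(-TR/T1))
```

with `dy_eff` from the PSF FWHM and `dx`, `dz` nominal. The square
root covers the total sampling duration `N_pe * N_par / BW` (the
standard sqrt-of-acquisition-time form). The value is unitless and
only ratios between protocols are meaningful; g-factor noise
amplification of under-sampled reconstructions is deliberately not
modelled.

Off-resonance displacement is `delta_f * ES_eff * N_pe * dy` (phase-
encode pixel shift times pixel size), exact and linear in both
`delta_f` and `ES_eff`.

## Synthetic data generator

The atomic unit is a 2D (ky, kx) plane, mirroring a reconstruction
that runs per ky-kz plane after a 1D transform along the fully
sampled readout. All Fourier transforms are unitary and centered
(k-space center at index `n//2`), so Parseval holds and noise levels
agree between domains.

* **Phantom**: nested ellipses (head, cortical rim, deep gray) with
  concentric ring ribbons playing white-matter tracts. Each ribbon
  carries an axially symmetric diffusion tensor with a prescribed FA
  (eigenvalues in closed form from FA and MD = 8e-4 mm^2/s) whose
  principal axis follows the ribbon tangent; the rest of the brain is
  isotropic. DWI contrast is `exp(-b g' D g)`. The baseline carries a
  smooth seeded phase.
* **Coils**: Gaussian reception profiles on a ring with low-order
  phase rolls, band-limited to a central 12x12 k-space window and
  RSS-normalized (RSS = 1 in support to 1e-6). A single coil is the
  constant unit map.
* **Shot phases**: band-limited random fields (central 8x8 k-space
  window, Hamming-tapered) scaled to a maximum amplitude, default
  1.5 rad; shot 0 is the zero-phase reference since only relative
  phases enter the forward model. b = 0 volumes are encoded without
  motion phases (no diffusion gradients, negligible motion
  sensitivity). The window keeps `exp(i*phase)` >99% inside a 32x32
  navigator even after the exponential map.
* **Sampling**: segment `s` owns ky lines `{s, s+N_seg, ...}`;
  acquired segments are an evenly spaced subset; partial Fourier
  removes the early-ky band. Masks are disjoint and tile k-space at
  full sampling.
* **Encoding**: `y_i = D_i F (P_i * S * image) + noise`, i.i.d.
  complex Gaussian of per-sample standard deviation sigma (no coil
  covariance). Navigators are the fully sampled central 32x32 k-space
  per shot at the same noise level — synthetic navigators need no
  GRAPPA step, a documented simplification. The calibration scan is
  the noise-free central 32x32 k-space of the baseline.

The reference end-to-end study is a 128x128 plane, 8 coils, 6 shots,
SNR 5 (mean brain baseline magnitude over sigma), seed 7, with two
b = 0 repeats (for noise estimation from repeats) and six DWI
directions. What the generator does *not* emulate: anatomical
realism, B0-field distortion, gradient nonlinearity, slab excitation
profiles, coil noise covariance, and motion beyond smooth per-shot
phases — so passing tests demonstrate correctness of the estimators
and solvers under the stated model, not robustness to those effects.

## Reconstruction

The unknown `x` is the fully sampled multi-coil k-space of one plane.
The objective is

```
sum_i || D_i F P_i F^-1 x - y_i ||^2  +  lambda1 || (G - I) x ||^2
                                      +  lambda2 || F^-1 x - z ||^2
```

solved by conjugate gradients on the normal equations, with `z` the
latest denoised image re-expanded to multi-coil form. The sign
convention for `P_i` is fixed by construction: the forward model
applies the same phase the generator applied, so data consistency
removes it; this is verified by the phase-amplitude-independence
property test rather than by notation.

* **SPIRiT kernel**: 5x5 cross-coil neighborhoods (own-coil center
  weight fixed at zero) fit on the central 32x32 calibration region by
  ridge regression with weight `0.01 * ||A||_2`. The kernel is applied
  as a per-pixel coil-mixing matrix in the image domain (exact for
  circular k-space boundary conditions), which makes each application
  one `einsum` instead of 64 convolutions; `(G-I)^H (G-I)` is
  precomputed per pixel for the normal operator.
* **Sensitivities**: apodized low-resolution coil images divided by
  their RSS (clamped below 5% of the peak RSS). This replaces an
  eigenvector-based (ESPIRiT-style) estimator, which is unnecessary
  for synthetic data with full support; the estimator is a plug
  point.
* **Coil compression**: SVD basis of the calibration data, applied
  consistently to shots, navigators, and calibration; the 8-coil
  target is a configuration default, not a constant.
* **Phase maps**: navigator k-space is Hamming-windowed (32x32),
  zero-padded, inverse-transformed; the phase of
  `sum_c m_ic conj(m_0c)` references every shot to shot 0 and cancels
  coil and object phase.
* **CG**: hand-written Hermitian conjugate gradients (relative
  residual tolerance 1e-6, max 100 iterations by default) so the
  residual log, divergence flag, and warm starts are first-class;
  outer iterations warm-start from the previous iterate, roughly
  halving inner iterations. An all-zero right-hand side returns zeros
  without iterating. The dense-matrix direct solve of the same normal
  equations on a 16x16 two-coil system is the correctness oracle.
* **Outer loop**: iteration 1 is plain SPIRiT (`lambda2 = 0`); then
  alternately denoise and re-solve. Two recombination modes mirror
  the two denoiser pathways: `magnitude_sos` denoises the
  root-sum-of-squares magnitude and multiplies by the coil maps
  (default weights `lambda1 = 10`, `lambda2 = 2`);
  `complex_sense` combines with the sensitivity maps, denoises the
  complex image, and re-multiplies (complex-denoiser pipelines
  typically want a slightly stronger prior, e.g. `lambda2 = 3`; the
  package default keeps 2). The weights are
  scale-free: every term of the objective is quadratic in `x`, so no
  data normalization is required.
* **Partial Fourier**: zero-fill or conjugate-symmetric fill after
  zeroth-order phase removal, applied to k-space before solving. A
  low-rank-completion approach to partial Fourier is out of scope; CS
  filling assumes a (near-)real image, so phase-corrupted data should
  prefer `zp`.
* **Denoiser contract**: shape-preserving, deterministic,
  finite-output callables in a registry; magnitude-only denoisers see
  `|image|` and the input phase is restored. The built-in `llr`
  denoiser does sliding-patch (8x8, stride 4) SVD hard thresholding at
  the Marchenko-Pastur noise-floor edge `sigma (sqrt(m) + sqrt(n))`,
  with sigma from a hint or a robust second-difference MAD estimate;
  a spatially uniform sigma is a known fidelity gap relative to
  g-factor-aware PCA denoisers. Block-matching and trained denoisers
  are intentionally not reimplemented; they attach via the registry.

Plug-and-play iterations with a non-expansive denoiser are only
empirically convergent; the per-outer-iteration objective is logged in
the diagnostics and audited, not asserted as a theorem.

## Metrics

Noise sigma is `std(rep1 - rep2)/sqrt(2)` over a mask from two b = 0
repeats. SNR is mean masked signal over sigma; angular CNR is the
masked mean of the per-voxel standard deviation across directions over
sigma. Sharpness is the masked mean gradient magnitude
(`sqrt(Gx^2 + Gy^2 (+ Gz^2))`, central differences, one-sided at
borders), normalized by each method's own sigma; the
sum-of-squared-gradients variant is available via the raw/normalized
split but the gradient-magnitude mean is the reported form, and sigma
is per-volume. NRMSE is the masked l2 error over the reference norm.
The KS statistic is the two-sample maximum ECDF difference on all
mask voxels (no binning), delegated to scipy with a brute-force pooled
scan as the test oracle. The DTI fit is per-voxel log-linear least
squares (6 tensor unknowns, >= 6 non-collinear directions), FA/MD from
eigenvalues with negatives clamped for FA only — a deliberate, minimal
stand-in for weighted production fitters.

## Problem sizes and determinism

Tests run the reference study at a 128x128 plane with CG tolerance
1e-5, 50 inner iterations, and 3 outer iterations — sizes chosen so
the full suite completes in a few minutes on one core while all
orderings of interest (denoiser prior vs plain SPIRiT vs post-hoc
denoising; R_eff = 1, 2, 3) are stable; exactness-grade checks use
noiseless 64x64 or 16x16 systems. Every stochastic step derives from
an explicit seed; reconstructions contain no randomness, so results
are bit-reproducible given fixture and configuration.

## Known limitations

Per-plane 2D reconstruction only (no kz/slab direction encoding, no
slab-boundary correction); no distortion or eddy-current correction;
no GRAPPA navigator reconstruction; circular k-space boundary for the
kernel (negligible for data that decays toward the k-space edge);
uniform noise maps; the relative-SNR model excludes g-factors. The
raw-data interface is the documented HDF5 layout — vendor raw formats
are not parsed.
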