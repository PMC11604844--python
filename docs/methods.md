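# Methods

## Problem

Dissolved-phase ¹²⁹Xe lung MRI quantifies pulmonary gas exchange from the
ratios of three spectrally distinct xenon pools: gas in the alveolar
airspaces (reference line), xenon dissolved in the alveolar membrane
(~+197.7 ppm) and xenon bound to red-blood-cell hemoglobin (~+217.2 ppm).
The dissolved pools carry only ~1–2 % of the gas-phase signal, so the
acquisition trades everything for SNR and speed: a 3D radial multi-echo
spectroscopic readout (flyback EPSI: each excitation reads the same spoke
at four echo times), a large flip on the dissolved resonances (22°) with a
tiny flip on the gas reservoir (0.22°), and a ~14 s breath-hold for 934
spokes at TR 15 ms. Compressed-sensing (CS) reconstruction of a spoke
subset can halve the breath-hold and suppress noise, provided the clinical
readouts — the RBC:M, RBC:Gas and M:Gas ratio maps — survive the
acceleration. This package implements the complete pipeline and exercises
it on digital lung phantoms.

## Forward model and simulator

The phantom is a pair of ellipsoidal lungs on an N³ grid (default N = 32,
FOV 40 cm) with a smooth parabolic interior profile, a gravity-like
ventilation gradient, ~10 % smooth random texture on the gas density, and
exact configured ratios ρ_rbc/ρ_m = 0.41 and ρ_m/ρ_gas = 0.0098 (healthy
defaults; both configurable, as are spherical "defects" that attenuate one
compartment locally). For echo e and k-point k_j on spoke s the simulator
evaluates

    y_e(k_j) = d(t_s) · Σ_c sin(α_c) · F{ρ_c}(k_j) · e^{i2πΔf_c TE_e} · e^{−TE_e/T2*_c} + v,

with v i.i.d. complex Gaussian noise. F is evaluated as the *exact* DFT
over the phantom support (chunked matrix products) whenever
support × samples ≤ 5·10⁸; larger problems use a 2×-oversampled
Kaiser-Bessel interpolation, with the exact DFT serving as the oracle in
tests. All echoes of one excitation share one spoke, so the per-compartment
DFT is computed once and reused across echoes.

Per-spoke decay d(t) models depolarization of the shared hyperpolarized
reservoir: d(t) = r^t · exp(−t·TR/T₁) with a per-excitation survival r
(default 0.99) and optional T₁. The decay applies to **all** compartments:
the dissolved magnetization is destroyed and re-created from the gas
reservoir every TR, so its amplitude tracks the reservoir, not its own flip
history (a literal cos²²° per-excitation decay of the dissolved pools would
extinguish the signal by ~30 orders of magnitude over 934 spokes, which no
acquisition shows). r = 0.99 yields an order-of-magnitude-scale decay
across the acquisition, strong enough to reproduce the characteristic
consecutive-versus-random spoke-ordering effect: discarding the depleted
end of the acquisition (consecutive selection at AF = 4) *raises* component
SNR despite the undersampling, while random temporal selection flattens or
reverses the trend.

Measurement noise defaults to σ = 0.022 (arbitrary units matched to the
unit-scale phantom densities). This value was calibrated once so that the
default phantom reconstructs with a gridding RBC SNR of ≈ 9, the healthy-
cohort operating point; SNR scales as 1/σ, so any other operating point is
one parameter away.

## Chemical-shift separation

Each k-sample carries a 4-echo measurement s = Φρ with
Φ[e,c] = e^{i2πΔf_c TE_e}·e^{−TE_e/T2*_c}. Separation is a per-sample SVD
pseudoinverse solve with condition-number logging (cond ≈ 10 for the
default model at the protocol TEs; an error names the condition number if
it exceeds 10⁸). Including the T2* magnitudes in Φ (the default; a flag
disables it) means the inversion also undoes inter-echo decay, which is why
the pipeline's gas-signal correction defaults to flip-angle-only (below).
Default resonance parameters are literature-typical for 1.5 T (membrane
+197.7 ppm, RBC +217.2 ppm at 17.66 MHz; T2* 20/2/2 ms) and every value is
overridable from config, emulating per-subject calibration. The
calibration-spectrum fitter recovers Δf, T2* and complex amplitudes from a
time-domain FID by variable projection (linear amplitudes, trust-region
refinement of frequencies and log-T2*), which avoids apodization and
zero-fill choices entirely and is deterministic from its initialization.

## Gridding reconstruction

Conventional reconstruction is Kaiser-Bessel convolution gridding:
density-compensate, convolve onto a G³ grid (G = smallest even integer ≥
1.2·N, so α_eff = 1.25 at N = 32), inverse FFT, deapodize, crop. The
kernel shape parameter is Beatty's minimal-aliasing choice
β = π·√((W/α)²(α−½)² − 0.8) with W = 8. Deapodization divides by the DTFT
of the integer-sampled kernel (exact for on-grid frequencies by
construction) with a 10⁻⁶·max floor against edge blow-up. Density
compensation defaults to the analytic |k|² radial law with the first-cell
average (Δk²/12) at the origin, normalized to unit sum; Voronoi-cell
weights (with mirror-point closure of the boundary cells) are available for
irregular sets. `grid_reconstruct` multiplies the unit-sum weights by the
convex-hull volume of the sample cloud (≈ π/6 for a full radial ball) so
that A*WA ≈ I and gridding, least-squares and CS images share one intensity
scale.

The same interpolation machinery, without density weights, is the encoding
pair A/A*: the adjoint is the exact conjugate transpose of the forward
(dot-product test ~10⁻¹⁵), while the forward approximates the true
non-uniform DFT to ~10⁻⁴ relative. Interpolation uses precomputed
(M × W³) index/weight tables with jitted gather/scatter loops — the
oversampled spectrum fits in cache, so both directions run in ~20 ms at
protocol scale on one core.

## Compressed-sensing reconstruction

Each separated channel is reconstructed by solving

    min_x ‖Ax − y‖² + λ₁‖x‖₁ + λ₂‖Tx‖₁

with Ψ = I (hyperpolarized lung images are natively sparse — there is no
background tissue signal) and T the stacked per-axis forward differences
with replicate edges (anisotropic TV, matching the literal ℓ₁ of the
objective). The solver is two-split ADMM: z₁ = x, z₂ = Tx, an inner
warm-started conjugate-gradient solve of (A*A + ρI + ρT*T)x = rhs, and
complex magnitude soft-thresholding with τ = λ/ρ (under which convention
the data term carries a ½; the traced objective is the exact functional the
updates minimize). When λ₂ = 0 the TV split is dropped — same minimizer,
faster convergence. Defaults: λ₁ = 0.003, λ₂ = 0.0003, ρ = 1, 50 outer
iterations, 10 inner CG iterations, stop at relative change < 10⁻⁵.

Two normalizations make those λ defaults transferable: the encoding
operator is rescaled to unit spectral norm (power iteration, cached), and
the data are scaled so the adjoint image has unit peak magnitude before
regularization, then unscaled. Without the spectral normalization the data
term Hessian is ~10⁶ × the penalty and a short inner CG cannot move the
solution. The printed objective uses the squared data term; an
"unsquared" reporting mode exists because the plain-ℓ₂ form also appears
in the literature — the two disagree only by the convention under which λ
is quoted.

ADMM is not a descent method, so the objective trace is only required (and
observed) to be non-increasing over its settled final 80 %. With λ = 0 the
solver converges to the least-squares solution; the correctness test runs
that comparison on a full-rank uniform-cube sampling, because on a radial
ball the corner k-space modes are unobserved, A*A is singular, and "the"
LS solution against which to compare is not unique.

## Ratio maps and masking

The lung mask thresholds the gridding membrane magnitude image at
μ_bg + 3σ_bg, with background statistics from three slices at each end of
the slice axis (six total) and removal of connected components smaller
than 25 % of the largest (keeps both lungs, drops speckle). Ratio maps are
voxelwise magnitude ratios on the mask; voxels whose denominator falls
below 1 % of the in-mask mean denominator are excluded and counted
(low-signal periphery voxels otherwise produce extreme ratios).

The gas image is first multiplied by sin(22°)/sin(0.22°) ≈ 97.56 to undo
the asymmetric excitation. A T2* readout correction — the ratio of mean
attenuation over the readout window, T2*/τ·(1 − e^{−τ/T2*}) per pool, or a
single midpoint evaluation — is implemented and tested, but the pipeline
default is flip-only: the matrix inversion above already removes per-echo
T2* decay in this forward model (no intra-readout decay is simulated), so
applying the window correction to simulated data would bias RBC:Gas and
M:Gas by ~20 %. On scanner data whose readouts do decay within each echo,
the window mode is the appropriate setting.

## Metrics

SNR = mean |signal| in the mask ÷ SD of the *real* channel over the six
outer slices; for pure complex Gaussian noise this converges to √(π/2),
which the tests verify against the analytic limit. NMAE is
100·mean|test − ref|/mean|ref| over the mask (a range normalizer is
available behind a flag). CV is the sample SD/mean. Pixelwise agreement is
ordinary least squares with the one-predictor adjusted R²; subject-level
agreement is Bland-Altman (bias ± 1.96 SD). Fidelity-versus-SNR behavior is
summarized by a log-log OLS power-law fit NMAE = a·SNR^k (optional
nonlinear refinement); on the default phantom sweep the fitted exponent is
negative (k ≈ −1.2 at AF = 2), i.e. fidelity degrades sharply once
gridding RBC SNR drops toward ~5.

## Problem sizes and determinism

The default study conditions are the full protocol: 934 phyllotaxis spokes
in randomized temporal order, 32 samples per center-out spoke (Nyquist for
the 32³ matrix; the readout length is not dictated by the protocol and is
exposed as a parameter), 4 echoes at TE = 0.57/1.27/1.97/2.67 ms. Unit
tests run reduced geometries (8³–16³, tens to hundreds of spokes) chosen so
the full suite and the acceptance script each finish in minutes on a single
core; the end-to-end checks still run the full 934-spoke, 32³ protocol.
Every stochastic stage (spoke ordering, phantom texture, measurement noise,
subset selection) draws from a seeded generator, and identical
configuration + seed reproduces bit-identical raw data and reconstructions.

## What the phantom does and does not establish

The phantom reproduces the geometry, spectral structure, SNR regime and
acquisition physics of the protocol, so it can validate the *pipeline*:
operator correctness, separation exactness, ratio preservation under
acceleration (mean ratios agree within a few percent between gridding and
CS at AF = 2), CS denoising (RBC SNR rises several-fold), defect-contrast
preservation, and the ordering/depolarization effect. It does not emulate
anatomical heterogeneity of gas exchange: the true RBC:M map is constant by
construction, so pixelwise between-recon regression mostly correlates
noise with smoothing and is uninformative here, and NMAE differences
between AF = 2 and AF = 4 are small (a piecewise-smooth object is exactly
what TV recovers well even at 4× undersampling). Cohort-level clinical
values (per-disease ratios, SNR distributions, repeatability) are outside
what any synthetic phantom can establish.

## Known limitations

- Single receive channel; no coil sensitivities, B₀/B₁ maps, or
  off-resonance blurring.
- No intra-readout T2* decay or gas-exchange kinetics (xenon uptake
  curves); the separation model and simulator are consistent by design.
- Anisotropic TV only; isotropic TV and wavelet sparsity are out of scope.
- The Voronoi DCF closes boundary cells by mirror points, which is exact
  for lattices but only approximate for irregular edge clouds.
- The depolarization model is a two-parameter reservoir decay, not a Bloch
  simulation; it is meant to produce the right ordering phenomenology, not
  quantitative polarization dynamics.
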