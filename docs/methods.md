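# Methods

This note documents the models, numerical choices and limitations behind
`dmipipe`. It describes what the code computes; every number quoted here is
produced by the test suite or `scripts/acceptance.py`.

## Signal model and conventions

Each voxel's FID is a sum of damped complex exponentials,

ρ(r, t) = Σ_m A_m(r) · exp(i2π f_m t) · exp(−π·lw(r)·t) · exp(iφ₀),

sampled at t = t_delay + n/BW (BW = 380 Hz, n = 0…95, t_delay = 2.0 ms).
Frequencies follow f_m = (ppm_m − ppm_ref)·γB₀ with γ = 6.536 MHz/T and the
carrier on water (4.8 ppm); at 7 T glucose (3.9 ppm) sits at −41.2 Hz. The
ppm axis is ppm_ref + f/γB₀, increasing with frequency. Amplitudes are
A_m = C_m · n_m · f_sat(TR, T1_m, α): concentration × deuterons per
molecule × Ernst steady-state saturation. Steady state is imposed
analytically — there is no Bloch simulation, no motion, and B₀
inhomogeneity enters only as an optional per-voxel frequency-offset map
(default zero).

Linewidth is parameterized as the absorption-mode Lorentzian FWHM
(lw = 1/(π T2\*)); magnitude-mode widths are √3 larger, which matters when
comparing to peak-picking measurements.

## Trajectory and reconstruction

Ring radii use a half-offset scheme r_i = k_max·(i+½)/(n−½) with
k_max = matrix/(2·FOV): no ring sits at k = 0 (whose angular Nyquist count
would be undefined) and the outermost ring reaches the matrix Nyquist
radius exactly. Each ring carries ⌈2π r_i/Δk⌉ angular samples (minimum 4).
Density-compensation weights are annulus-area/count, optionally
Hamming-windowed, normalized to Σw = 1. Temporal interleaving used on
hardware to reach the spectral bandwidth is abstracted away: every ring
yields the full 96-point FID.

Reconstruction is the adjoint NUDFT evaluated directly (matrices ≤ 28×28
make the O(N_k·N_vox) cost trivial and the operator exact, so the
degenerate-Cartesian trajectory reproduces the FFT inverse to ~1e−15).
Because the rings cover a disk rather than the Cartesian square, the
adjoint applies a quadrature scale (covered k-area × voxel area ≈ π/4) so
extended objects keep their amplitude; a point source then reads ~π/4 low,
the standard aperture trade-off. With this scale the amplitude NRMSE of a
smooth object is ~2% and of the hard-edged default phantom ~9% (Gibbs
ringing), both inside the 15% bound asserted in tests.

The acquisition delay is handled as a first-order spectral phase ramp
(exp(−i2πf·t_delay) under the numpy forward-FFT sign convention), not by
back-extrapolation. The spectral fit pushes its model through the *same*
transform, so the convention cancels exactly.

## Coil combination

WSVD: per voxel, whiten the coil×time matrix with the inverse Cholesky
factor of the noise covariance (estimated from the acquisition's own
noise-only block; ridge 10⁻⁶·trace/n added when the condition number
exceeds 10⁶, as a loop + butterfly pair can be strongly correlated), take
the rank-1 SVD, and fix the global phase so the first FID point is real
and non-negative. Two identical coils with independent equal noise gain
√2 in SNR (measured 1.41 ± a few % over 100 seeded voxels).

## Denoising

tMPPCA operates on complex FID-domain data after coil combination
(config-switchable, but per-coil denoising is not the default): 5×5×5
spatial patches (clipped to the grid), stride 2, tensor modes
(patch-voxels, FID-time, dynamics), two sequential truncation sweeps per
patch, uniform averaging of overlapping patches. The rank rule accepts the
smallest p whose trailing eigenvalue spread fits the Marchenko–Pastur bulk
width 4σ̂²√((R−p)/L), with a 1.05 finite-size allowance on the asymptotic
edge (the empirical pure-noise spread exceeds the asymptotic width by <5%
at the 99th percentile for the matrix shapes that occur here) and an
exact-zero floor for noiseless input. σ̂ is reported per real/imaginary
component.

On the default dynamic phantom (8 frames at spectral SNR ≈ 7) tMPPCA
removes ≳90% of the RMSE to the noiseless truth and shifts the mean fitted
water FWHM by well under 1 Hz. Synthetic data are exactly low-rank, so
this gain is an upper bound: in vivo data with motion, B₀ drift and
non-Gaussian structure will benefit less. Passing these tests shows the
estimator and truncation are correct, not that real kidneys denoise this
well.

## Spectral fitting

The basis is analytic — two singlets with Lorentzian (optionally Voigt)
lineshape; ²H J-structure is unresolvable at ~14 Hz linewidths at 7 T, so
no quantum simulation is warranted. The model FID is built on the true
sample times and transformed exactly as the data (unitary FFT + delay
ramp), making the noiseless round trip exact and fitted amplitudes refer
to t = 0. Parameters per resonance: amplitude (≥0), frequency shift
(|δ| ≤ 20 Hz), FWHM (2–50 Hz); shared: one zero-order phase and a constant
complex baseline (²H spectra have no macromolecular background). Voigt
adds one shared Gaussian width. `scipy.optimize.least_squares` with bounds
and tight tolerances; non-convergence is flagged, not raised.

CRLBs come from the Fisher information F = JᵀJ/σ² of the stacked
real/imaginary Jacobian at the solution, reported as percent of the
amplitude; σ is the off-resonant (≥100 Hz from both resonances) real-part
SD unless supplied. Across 200 noise realizations the empirical amplitude
scatter sits within a factor ~1.1 of the mean reported CRLB. SNR is the
fitted water peak height over the off-resonant noise SD (raw peak height
available as an alternative).

## Quantification

Internal referencing against the pre-tracer scan's fitted water amplitude,
voxel-matched. The natural-abundance HDO concentration is
2 × 1.56·10⁻⁴ × 55 510 mM × 0.80 ≈ 13.9 mM (abundance and water-content
fraction both configurable). Relaxation assumptions (brain-tissue values,
none being available for kidney at 7 T): T1 335/70 ms, T2 36/36 ms for
water/glucose. Saturation and T2-delay corrections are individually
switchable so each factor can be verified in isolation; with equal T2s the
delay factors cancel in the ratio. The fitted amplitudes are already
extrapolated to t = 0 through the fitted linewidth, so the T2 correction
matters only insofar as assumed T2s differ between metabolites.

Exclusion filters: amplitude CRLB strictly >50% (ties retained) and
glucose >5 mM (≡ 90 mg/dL increase, guarding against gastrointestinal
signal bleed). Counts are integers and exactly reproducible. B1⁺ maps
(double-angle method, arccos(S₂α/2Sα)) are diagnostic only and not applied
as a per-voxel flip correction by default.

## Phantom defaults (the study conditions)

Grid 22×22×21 over 270×270×260 mm³ (~1.86 mL voxels; the 28×28×27 /
~0.90 mL protocol is available); abdomen ellipsoid plus two kidneys
(28×22×55 mm semi-axes, ~74 voxels each at 1.86 mL); water everywhere at
the natural-abundance level; renal glucose following a gamma-variate
peaking at 2.0 mM 37 min after intake; linewidths 14 Hz (kidney) / 15 Hz
(body); two coils with Biot–Savart-like posterior falloff and correlation
0.2; per-component noise SD 200 (k-space units), chosen once so the
un-denoised pipeline lands in the reported in vivo quality regime
(kidney-mean spectral SNR ≈ 8, FWHM ≈ 13–14 Hz). Dynamic protocols use a
pre-tracer baseline frame plus ~8.5 min frames timestamped at their
midpoints.

What the phantom does **not** emulate: respiratory/cardiac motion, B₀
drift, partial-volume mixtures beyond voxelization, chemical-shift
displacement, and spatially varying noise. Tests passing on this phantom
validate the algorithms and their book-keeping, not in vivo image quality.

## Problem sizes and determinism

Full-protocol checks run the 1.8 mL matrix with a baseline + 7 frames
(~2 min on one CPU); unit tests use 8×8×4 to 10×10×8 grids. All
randomness flows through `numpy.random.default_rng` seeded from the
phantom seed (noise per frame from (seed, frame); coil phases from the
seed alone so the array is fixed across an "exam"); identical seeds give
bit-identical k-space.

## Known limitations

- The adjoint-with-DCF reconstruction is not an exact inverse off the
  Cartesian grid; residual ~2% amplitude error on smooth objects, Gibbs
  ringing at compartment edges.
- The fold-change and COV figures of a dynamic run are
  acquisition-dependent; the package asserts recovery of *programmed*
  dynamics, not any particular in vivo value.
- Glucose at baseline (zero truth) fits to a small positive amplitude
  (rectified noise); the CRLB filter removes most such voxels, and
  kidney-mean baseline estimates of ~0.2 mM at SNR 8 are expected.
- One noise covariance per acquisition is estimated from its own noise
  block; no reference-scan reuse.
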