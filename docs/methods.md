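# Methods

This note documents the models implemented in `teangio`, the parameter
choices that matter, the synthetic-data generator, and the package's
numerical conventions and known limitations.

## Protocols and timing conventions

Both presets use a 10 ms SPGR TR, 12 excitations per readout frame (120 ms
temporal resolution), a 2 ms spoiler after labeling, and a first excitation
centered half a TR after the spoiler. The sequential protocol labels for
360 ms and reads nine LL frames (N = 108); the time-encoded protocol labels
three 360 ms blocks (1080 ms total) under a 4×3 Hadamard pattern and reads
three frames (N = 36). Effective timepoints are quoted as label duration +
post-labeling delay, using the mean excitation-center time within each
frame; both presets then share the series 422, 542, …, 1382 ms, with the
earliest labeled block decoding to the latest timepoints.

Hadamard conventions: control = +1, label = −1; the 4×3 matrix is the
order-4 Hadamard matrix minus its all-control column. A decoded block is
`(2/n_enc) · Σ_i sign(i) · image_i`, which makes a decoded difference equal
in amplitude to a plain pairwise control−label subtraction, so sequential
and time-encoded images live on the same signal scale. Under this
normalization the decoded noise SD of the 4×3 scheme equals the per-image
noise SD, which also equals the subtraction noise of a two-average
sequential scan — the two protocols are noise-matched at matched scan time.

## Flip-angle design

Under constant supply, perfect spoiling, and every spin seeing every pulse,
the acquired signal at excitation *n* is `sin θ(n) · Π_{m<n} cos θ(m)`.

* **CFA (max-min)**: maximizing the last-excitation signal
  `sin θ cos^{N−1} θ` gives `θ* = arctan(1/√(N−1))`; the equivalent
  half-angle form `π − 2 arctan(√N + √(N−1))` is verified identical in the
  tests. 5.5° at N = 108, 9.6° at N = 36.
* **CFA (max-mean)**: maximizing the mean signal
  `sin θ (1 − cos^N θ)/(N(1 − cos θ))` has no closed form and is solved by
  bounded scalar minimization (tolerance 1e−9 rad): 8.7° and 15.1°. It
  buys a 15%/14% higher mean at the cost of a 25% lower final-excitation
  signal, which is why max-min is the default (distal vessels fill last).
* **VFA**: the backward recursion `θ(n) = arctan(sin θ(n+1))` from a chosen
  final angle produces an exactly constant acquired signal, equal to
  `sin θ(1)`; with a 90° final angle this is `1/√N`. The default final
  angle is 30° (SAR and slice-profile practicalities), costing only 1%
  (Seq) / 4% (TEnc) of the mean signal.

Angles are radians internally, degrees only at I/O boundaries. Reported
percent comparisons are rounded half-away-from-zero to integers.

## Dispersed-bolus signal model

The labeled bolus is smeared by a gamma transit-time kernel (shape
`1 + p·s`, rate `s`) and decays with blood T1 (default 1.65 s); the
integral over the labeling window has a closed form in the regularized
incomplete gamma function, which is what the package evaluates (an
adaptive-quadrature path and a Riemann-sum oracle back it in the tests).
Without dispersion, each labeled element is observed exactly one transit
time after labeling, so the model plateau is `A·exp(−Δt/T1)` — the reason
the VFA recursion needs no T1 term. RF attenuation generalizes the
constant-flip-angle factor to the cumulative cosine product of the actually
played schedule, indexed by the excitation at (or most recently before) the
evaluation time; signals are evaluated at excitation centers where this
flooring is exact. The lower integration limit is clipped at zero (causal
kernel). For the time-encoded protocol each block's bolus uses its own
labeling window while sharing the 36-excitation attenuation history, and
decoded timepoints are assembled in block order.

Two standard parameter sets are built in: no dispersion (s = 10⁴ s⁻¹,
p = 0) and moderate dispersion (s = 10 s⁻¹, p = 0.1 s); comparisons default
to arrival 650 ms and frame-averaged (120 ms) decoded signals.

## Background suppression

A presaturation at labeling onset plus two inversion pulses timed by the
classic two-pulse nulling formula (T1_opt = 0.7 s, targets 0.7/1.4 s)
control the tissue signal. Tissue during the readout follows the
saturation-recovery recursion `Mz(n) = 1 − (1 − Mz(n−1) cos θ(n−1)) e^{−TR/T1t}`
with `Mz(1) = 1 − exp(−t_null/T1t)`, instantaneous pulses and perfect
spoiling; T1t defaults to 1.118 s (white/gray-matter average). The
optimized null time minimizes `max_n |Mz(n) sin θ(n)|` over a 1 ms grid on
(−T1t·ln 2, 1 s]. Feasibility treats the computed inversion times as pulse
onsets: each 10.24 ms pulse must finish inside the labeling period and the
two must not overlap. Under this convention the optima are −87 ms (Seq-LL
VFA) and −217 ms (TEnc-LL VFA), both feasibility-bound at the
last-pulse-inside-labeling constraint, which is why they are insensitive to
T1t above 0.5 s. Ties on the grid break toward the smallest null time. The
model deliberately excludes the inversion pulses' own imperfections
(adiabatic efficiency, profiles); the timing formula is used for
feasibility and for emitting scanner timings only.

## Synthetic phantom and k-space generator

The generator emulates a 2D radial SPGR angiography acquisition at desk
scale. Defaults (all configurable): 96×96 matrix, three curved vessels of
1.2 px radius with arrival times 0.30/0.55/0.80 s (early/middle/late),
moderate dispersion (s = 10 s⁻¹, p = 0.1 s), unit vessel amplitude; static
tissue inside an elliptical brain mask split into two T1 classes
(0.791/1.445 s) by thresholded smooth noise; 8 smooth complex coil maps
(Gaussian lobes around the FOV with low-order phase); 13 segments × 12
spokes = 156 evenly distributed spokes (≈ fully sampled at 96², matching
the fully sampled in vivo regime), the same spokes acquired for every
encoding and average before the next segment; additive complex Gaussian
noise; and a global B0-drift phase linear in acquisition time.

Spoke data are synthesized by exact discrete Fourier evaluation of the
component images (each vessel, each tissue class) — not by the gridding
code used in reconstruction, so forward and inverse models share no
interpolation error. Vessel contributions enter encoding *i* as
`Σ_j sign(i,j)/2 · S_j(t)` so decoding recovers each block's bolus exactly;
label and control differ only in the vessel sign. The component k-space
depends only on geometry and can be cached and reused across protocol
variants and undersampled subsets.

What the generator does **not** emulate: physiological pulsatility, motion,
spatially varying off-resonance, imperfect inversion pulses, slice
profiles, or realistic anatomy. Passing the phantom-based tests therefore
demonstrates the correctness of the encoding/decoding, reconstruction and
quantification chain under thermal noise and global drift — not robustness
to physiological confounds.

## Reconstruction

The chain is: per-spoke scalar phase correction against the first acquired
condition (inner product over all samples and coils of the matched spoke);
density compensation by fixed-point iteration on the gridding kernel (10
iterations, unit-mean normalized — the absolute image scale of a gridding
reconstruction is arbitrary); adjoint gridding with a Kaiser–Bessel kernel
(width 5, 2× oversampling, Beatty parameter — chosen so the operator
matches a direct adjoint DFT to ~1e−4, comfortably inside the 1e−3 oracle
bound used in the tests); adaptive-combine coil maps (per-pixel dominant
eigenvector of the local coil covariance, kernel `round(10 mm/res)` px,
threshold zero, first-coil phase reference); Roemer combination; complex
averaging of repeats; Hadamard decoding or pairwise subtraction; magnitude.
Decoding happens after coil combination and averaging, before the
magnitude operator, matching the stated chain order.

## SNR quantification

Vessel masks follow a five-step heuristic on the temporal-mean image:
rescale to [0, 1]; subtract a disk-radius-2 morphological opening inside
the brain mask; saturate the top 1% of in-brain voxels; binarize at 50% of
Otsu's threshold (256 bins); drop 8-connected clusters under 10 voxels.
Background noise is estimated from four corner squares (10% of the matrix
each, outside the brain) as RMS/√2 of the magnitude samples — the
per-channel complex SD under the Rayleigh model. (A "RMS/2" variant
sometimes quoted for this estimator is inconsistent with its own Rayleigh
rationale, E[M²] = 2σ²; the √2 form is implemented and verified unbiased
on simulated Rayleigh samples.) SNR is the mean vessel-mask signal across
timepoints divided by that SD. Protocol comparisons across subjects use
two-tailed paired t-tests with Holm–Bonferroni step-down correction.

## The matched-phantom SNR study

The test suite reconstructs four scan-time-matched acquisitions of one
phantom (Seq-LL and TEnc-LL, CFA and VFA; two averages for Seq-LL versus
four encodings for TEnc-LL), plus a 2× angularly undersampled TEnc-LL VFA
scan (7 of 13 segments) against a single-average Seq-LL VFA scan. Study
conditions: k-space noise SD 0.08 (vessel SNR ≈ 20–30, a realistic
angiographic regime), B0 drift 0.01 rad/s, default 100 ms nulling, phase
correction on. Asserted properties: the SNR ordering TEnc-VFA > TEnc-CFA >
Seq-VFA > Seq-CFA, and higher SNR for undersampled TEnc-LL than for
single-average Seq-LL.

A caveat on the TEnc/Seq VFA SNR *ratio*: with noise-matched protocols the
constant-supply prediction is 1.69, and that value is an upper bound for
this study, not an attainable mean. Two mechanisms pull the measured ratio
below it. First, the corner background ROIs contain the collective PSF
sidelobe energy of the vessel pixels themselves — a floor proportional to
each protocol's own signal (vessel-mean to corner-RMS ratio ≈ 17 in a
noise-free reconstruction, insensitive to spoke count, DCF iterations, and
bolus smoothness), which compresses SNR ratios toward 1. Second, Rician
bias adds a common offset to both vessel means at near-zero-signal
timepoints. In vivo measurements can exceed 1.69 because the longer
sequential readout carries more physiological noise; the generator
deliberately contains no physiological noise, so the study reports the
ratio but asserts only the ordering. At the frozen conditions the measured
ratio is ≈ 1.3.

## Numerical conventions

* Bolus integral: closed form via `scipy.special.gammainc`; quadrature
  tolerance 1e−10 on the oracle path.
* Grid searches: CFA cross-check at 0.01° steps; BGS at 1 ms with
  smallest-value tie-break; refinement stability verified at 0.1 ms.
* Gridding: image center at pixel `M//2`, k in cycles/pixel, |k| ≤ 0.5;
  forward/adjoint are exact conjugate transposes of one another.
* Degenerate inputs: empty integration windows return 0; zero-norm
  reference spokes are left uncorrected with a warning; zero-signal pixels
  get first-coil unit sensitivity; all-zero maps combine to 0.
* RNG: `numpy.random.default_rng` seeded explicitly everywhere; identical
  seeds reproduce identical k-space bit-for-bit.
* Heavy syntheses may use complex64 (~1e−5 relative accuracy); all oracle
  tests run in complex128.
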