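# Methods

## The problem

Raster image correlation spectroscopy (RICS) extracts diffusion
coefficients from confocal image series by exploiting the fact that a
raster scan embeds a time axis in space: adjacent pixels along a line
are separated by the pixel dwell time τ, so the spatial autocorrelation
function (ACF) of the intensity fluctuations mixes the scanning
geometry with the dynamics of the fluorophores. A whole-image ACF,
however, yields a single average D per image; its spatial resolution is
limited to the few-µm scale because the ACF model breaks down on small
crops. Local RICS (L-RICS) instead computes a *masked* ACF around every
pixel, summarizes each one by a single fit-free shape descriptor — the
phasor phase — and converts phases into diffusion coefficients through
calibration curves built with the package's own Brownian-motion
simulator. The result is a per-pixel diffusion map with a spatial
resolution set by the mask size (m·δx, e.g. 500 nm for m = 25 and
δx = 20 nm).

## Global RICS model

For 3-D free diffusion and a Gaussian observation volume (lateral 1/e²
waist w0, axial waist wz = 3·w0 by default), the x-axis ACF is

    G(ξ) = G(0) · exp(−(|ξ| K_s)² / (1 + K_t(ξ)))
                · (1 + K_t(ξ))⁻¹ · (1 + (w0/wz)² K_t(ξ))^(−1/2)

with the spatial sampling constant K_s = δx/w0 and the temporal
sampling constant evaluated at the elapsed time of the lag,
K_t(ξ) = 4 D τ |ξ| / w0² (equivalently τ·|ξ|/τ_D with the diffusion
time τ_D = w0²/4D). The per-lag time mapping τ → τ·|ξ| inside the
lag-dependent factors is the standard RICS convention; with it the
model reduces correctly to the pure scanning Gaussian exp(−(ξ K_s)²)
as D → 0. Only the x component is modelled: at the settings of
interest the line time (ms) is far longer than τ_D (sub-ms), so the
η ≠ 0 part of the ACF carries no usable correlation.

The fit has two free parameters (G(0), D). The ξ = 0 point contains
the white shot-noise autocorrelation and is excluded by default.
Initialization: G(0) from the first lag, D from the lag at which the
ACF has decayed to half of it. Optimization is bounded least squares
(`scipy.optimize.curve_fit`); non-convergence is reported explicitly,
never silently.

## Local ACF and its conventions

For every pixel (i, j) the m×m sub-image around it is autocorrelated
per frame, normalized by the squared sub-image mean of that frame,
minus one, and averaged over N frames; the η = 0 row, restricted to the
first L = (m+1)/2 lags, is the local 1-D ACF. Deliberate conventions:

- **Circular correlation, no zero padding.** The masked FFT
  autocorrelation wraps within the mask. Any fixed convention works
  because the calibration curves are built with the identical code
  path and absorb convention-dependent deformation; the package
  records the convention (`ACF_CONVENTION = "circular"`) in every
  calibration and refuses to mix conventions. The global ACF, which is
  fitted against the closed-form model rather than a calibration, uses
  zero-padded FFTs with per-lag overlap normalization instead.
- **Zero-lag replacement.** G(0) contains the uncorrelated shot-noise
  spike; before any phasor analysis it is replaced by the ξ = 1 value.
- **Border handling.** Pixels within ⌊m/2⌋ of an image border have no
  complete mask and are NaN in every downstream map.
- **Batched = pixel-wise.** The production implementation computes all
  masks of a frame at once with integral-image (summed-area) sliding
  sums; it is tested to agree with the per-pixel FFT route to machine
  precision, and both against explicit double sums.

## Phasor phase

Each L-point local ACF is reduced to the normalized first harmonic:
g = Σ G(ξ) cos(2πξ/L) / Σ G(ξ), s = Σ G(ξ) sin(2πξ/L) / Σ G(ξ),
φ = atan2(s, g) — i.e. the k = 1 DFT coefficient over the k = 0
coefficient, with s taken as minus the imaginary part. With this sign
convention slowly decaying ACFs (slow diffusion) give larger positive
phases. The phase is invariant under amplitude rescaling of the ACF,
which is what makes it robust to concentration and brightness
variations across the image. Pixels whose zeroth harmonic vanishes
have no defined phase and are flagged.

Phase noise is quantified as σ_φ, the standard deviation over the
phase image of a uniform sample; the relative error σ_φ/⟨φ⟩ (with ⟨φ⟩
the spatial mean) decreases as N^(−1/2) in the number of averaged
frames, which the acceptance suite verifies.

## Calibration and inversion

For fixed (K_s, m, ACF convention) the mean phase of a uniform
simulation depends only on K_t. The calibration runs one simulation
per diffusion coefficient on a default grid of 9 values spanning
4–36 µm² s⁻¹, records mean phase versus K_t, rejects non-monotone
sample sets, and fits the three-parameter exponential decay

    φ(K_t) = a · exp(−K_t / b) + c.

Calibration simulations use high molecular brightness (3 MHz) and many
frames so that calibration noise is negligible against measurement
noise. The inversion is the exact analytic inverse of the stored fit,
K_t = −b ln((φ − c)/a), followed by D = K_t w0²/(4τ); τ may be a
scalar, a per-column profile or a full per-pixel map. Phases outside
the invertible range are flagged out-of-range (clamping to the sampled
K_t endpoints is available but opt-in). Calibrations are persisted as
JSON with their samples, fit, conventions and simulation provenance,
and refuse to apply to a phase map with a different mask size, mask
kind (square vs line) or K_s.

Line scans use 1×m masks whose normalization statistics differ from
square masks, so they get their own calibration curves
(`mask_kind="line"`); mixing the two kinds is a hard error.

## The simulator

Point emitters diffuse in a periodic box extending 2 µm beyond the
scanned field laterally and ±3·wz axially (periodic wrapping conserves
concentration; recovery results are insensitive to this choice at
these margins). Time advances pixel by pixel: the sample at (frame k,
line y, column x) occurs at t = k·T_frame + y·T_line + Σ_{c<x} τ(c),
and between consecutive samples each molecule takes an independent
Gaussian step of per-axis variance 2·D·Δt (intra-dwell motion is
neglected — the dwell time is a sampling interval). Per-column dwell
profiles, line/frame retraces (default 0), and per-pixel
diffusion-zone maps are supported; a molecule uses the D of the zone
under its current lateral position, with out-of-field molecules taking
the nearest zone's value. The expected pixel signal is
Σ B·τ(x)·exp(−2r²/w0² − 2z²/wz²); shot noise draws Poisson counts
around it. Gaussian tails are truncated at 4 waists (attenuation
< e⁻³², far below shot noise).

Default concentration: the reference acquisition is 2500 molecules in
the box belonging to a 256×256 px / 20 nm field (≈ 10.4 µm⁻³, about
0.7 molecules in the focal volume); scaled-down fields keep this
concentration rather than the absolute count. All randomness flows
from one seeded `numpy.random.Generator`, which the compiled scan
kernel consumes directly; a stack records its seed, molecule count and
box in its metadata, and identical configurations reproduce identical
stacks bit for bit.

What the simulator does *not* emulate — and therefore what passing
tests cannot certify on real data: triplet/blinking photophysics,
photobleaching, anomalous or confined diffusion, binding, detector
afterpulsing and dead time, realistic cellular background and
autofluorescence, and mechanical drift. The synthetic benchmarks
establish that the estimator chain is correct and self-consistent
under pure Brownian motion with shot noise.

## Background subtraction

Correlations are computed on fluctuations. Two schemes: subtraction of
the per-pixel temporal mean (exact removal of immobile structure;
used for simulations and stationary samples) and subtraction of a
per-pixel temporal moving average (window default 10 frames,
configurable; appropriate when slow drifts or bleaching are present).
In both cases the mean of the subtracted component is added back as a
constant, so the overall mean — the normalization denominator
downstream — is preserved exactly. The moving window is centred and
*shifted* (not shrunk) at the series edges: it keeps its full length,
avoids phase lag in the background estimate, and makes
`window = n_frames` degenerate exactly into global-mean subtraction.
Any window comfortably longer than the diffusion correlation time
expressed in frames (which is ≪ 1 frame here) leaves fluctuations
intact.

## Scanner-speed characterization and correction

On non-linear scanners the dwell time — the inter-pixel lag δx/v, not
the photon integration time — varies along the line, which biases
constant-dwell diffusion maps toward higher values where the scanner
is slow (the image borders for a galvo). Because the local analysis
only needs the speed constant across one mask, the phase map of a
uniform sample of known D exposes τ(x): the phase image is averaged
along y, smoothed with a polynomial over x (degree 4 by default;
smooth galvo speed profiles are low-order, and degree 4 reproduces the
sinusoidal edge-slowdown profile to < 0.5% systematically), inverted
through the calibration to K_t(x), and scaled as
τ(x) = K_t(x)·w0²/(4D). The 2-D dwell map copies τ(x) along y.
Correction is simply the phase → D inversion with that per-column
dwell.

The characterization stack should be a *bright* uniform sample: at
GFP-level brightness (24 kHz) the per-column phase noise, amplified by
the shallow slope of φ(K_t) at small K_t and by the variance
inflation of polynomial fits near the interval ends, leaves dwell
errors of tens of percent at any feasible acquisition length, whereas
a calibration-grade sample (3 MHz, as used for the calibration curves)
brings the closed-loop profile error below 5%. The acceptance suite
runs the closed loop at 3 MHz accordingly.

## Line-RICS

Repeated single-line acquisitions (N_lines × 1 × nx) reuse the same
machinery with 1×m masks, averaging over lines instead of frames. For
N lines the acquisition time is X·N·τ instead of X·Y·N·τ, so line maps
reach a given phase noise about Y times faster, at the cost of
reducing the map to one dimension. Profiles can be segmented by a
normalized (min-max over the analyzed region) second-channel intensity
at a 0.5 threshold, and diffusion histograms fitted with one or two
Gaussians (least squares on a Freedman–Diaconis density histogram;
an EM mixture fit on the raw values serves as an independent
cross-check in the tests).

## Problem sizes

Reference acquisition settings throughout: δx = 20 nm, τ = 50 µs,
w0 = 0.16 µm, wz/w0 = 3, K_s = 1/8, B = 24 kHz (GFP-like) or 3 MHz
(calibration-grade). The package's own benchmark sizes, chosen to keep
a full run on a single core in the tens of minutes while leaving
enough independent mask-sized patches for stable statistics:

- phase-noise study: 128×128 px (acceptance script; 3 replicates) or
  96×96 px (test suite; 2 replicates), 100 frames, m ∈ {21, 25};
- three-zone benchmark: 256×256 px / 100 frames with 500 molecules in
  the script, 192×96 px / 250 frames at the default concentration in
  the test suite (zones of 32 rows each);
- calibration: 9 diffusion coefficients, 64×64 px, 150–250 frames;
- recovery: 96×96 px, 250 frames, D ∈ {8, 16, 24, 32} µm² s⁻¹;
- scanner loop: 128×128 px, 250 frames, 12→18 µs edge-slowdown.

Phase maps are spatially correlated on the mask scale, so the number
of independent patches — (valid size / m)² — not the raw pixel count,
controls the sampling error of map means; fields below ~96 px leave
only a handful of patches and noticeably seed-dependent means.

## Known limitations

- The phase → D mapping is purely empirical (simulation-built); there
  is no closed-form φ(K_t) theory, and a calibration is only valid for
  its exact (K_s, m, mask kind, ACF convention).
- One apparent D per pixel: no multi-component or anomalous-diffusion
  decomposition; heterogeneity below the mask footprint is averaged.
- The sample must be stationary over the frames being averaged.
- Exponential-decay calibration extrapolates poorly outside the
  sampled K_t range; out-of-range phases are flagged rather than
  extrapolated.
- Even-sized masks and y-axis (line-time) correlations are
  unsupported by design.
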