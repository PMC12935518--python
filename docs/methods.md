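# Methods

## The measurement problem

Digital radiography images taken with a flat-panel detector carry noise
from three sources: quantum (photon-counting) noise whose variance scales
with dose, electronic readout noise that does not, and static structural
noise from detector inhomogeneities. The noise power spectrum (NPS)
describes how that noise is distributed over spatial frequency; comparing
the NPS before and after a noise-reduction algorithm tells you not just
*how much* noise the algorithm removed but *at which frequencies* — which
matters because an algorithm that only removes high-frequency noise can
look impressive on a variance metric while leaving clinically relevant
mid-frequency mottle untouched.

## NPS estimation

Given an image with pixel pitch Δx = Δy (mm), a square analysis ROI
(default 1024×1024 px) is cropped at a chosen centre and subdivided into
local ROIs of S×S px (default S = 256, non-overlapping → 16 tiles; a
half-stride grid of 49 tiles is available as a variance-reduction option).
For each tile:

1. **Detrend.** The least-squares 2D polynomial surface of total degree
   ≤ 2 (terms 1, x, y, x², xy, y²) is subtracted, isolating the stochastic
   fluctuation from smooth background and fixed-pattern trends. The degree
   is configurable 0–2.
2. **Periodogram.** With no window or taper,

       NPS(u, v) = (Δx·Δy / S²) · |DFT2(fluctuation)|²,

   in (pixel value)²·mm². This normalisation satisfies Parseval exactly:
   Σ NPS · Δu·Δv equals the residual mean square of the tile, and white
   noise of variance σ² sits at the flat level σ²·Δx·Δy.

The per-tile periodograms are averaged, then reduced to 1D by the radial
frequency method: bins of width Δu = 1/(S·Δx) centred at k·Δu, each 2D
grid point assigned to the nearest bin centre by its radius √(u²+v²),
points beyond the axis Nyquist 1/(2Δx) discarded so the axis ends at
Nyquist (128 bins at S = 256). The DC point is excluded by default;
the two frequency-axis lines can be excluded as well (off by default).

### Detrend suppression of the lowest bins

Subtracting a fitted polynomial is a linear projection, so it removes a
computable fraction of every Fourier mode. `detrend_suppression(S, order)`
returns the exact expected white-noise suppression factor
D(u,v) = 1 − Σⱼ |q̂ⱼ(u,v)|²/S² (qⱼ an orthonormal basis of the polynomial
span): D ≈ 0 at DC, ≈ 0.56 in the first radial bin for degree 2, and ≈ 1
from the third bin on. Consequences worth knowing:

* absolute-level comparisons should either weight bins by their grid-point
  counts (the count-weighted band mean is unbiased) or fold D into the
  prediction — the tests do both;
* the NPSIF, being a ratio of spectra measured with the same detrend,
  cancels D;
* for strongly coloured spectra (e.g. heavy blur, dynamic range ≳ 100×
  across the band) periodogram leakage adds a few-percent excess in the
  weakest bins; the transfer-function validation therefore uses a moderate
  kernel (σ = 0.6 px, ~10× dynamic range) where agreement is ~1% RMS.

## NPSIF

NPSIF(u) = NPS₋(u) / NPS₊(u), the ratio of the radial NPS without
processing to the radial NPS with processing, computed bin-wise on a
shared frequency grid. Values > 1 mean noise reduction at that frequency.
Bins where the denominator falls below a relative guard (default 1e-12 of
its maximum) are masked rather than reported, because the ratio is
meaningless where the processed image retains essentially no noise power.
`band_mean` summarises a curve over a frequency band by the arithmetic
mean of unmasked bins.

## Residual-noise procedure for structured scenes

For scenes with anatomy, three repeat frames are acquired under identical
settings. The three cyclic pairs (1,2), (2,3), (3,1) give three difference
images; static content cancels exactly in each, while independent noise
adds in power. The NPS of each difference is divided by 2 (in the power
domain) and the three corrected spectra averaged per bin. Each frame is
used in two pairs, so the three spectra are positively correlated: the
average is unbiased, but its variance is larger than three independent
estimates would give (it is still never worse than a single pair — tested).
The cyclic pairing is a convention choice; any fixed set of three distinct
pairs has the same expectation. `difference_diagnostics` reports the mean
and residual planar trend of a difference image, the cheapest check that a
nonlinear processing step has not broken the cancellation assumption.

For the NPSIF of structured scenes the default is the ratio of the
pair-averaged spectra (ratio of means), which is less noise-biased than
averaging per-pair ratios; the per-pair variant is available behind
`per_pair_ratio`.

## Synthetic detector model

`SyntheticSpec` generates frames as

    mean_signal·dose_factor + background + fixed_pattern
      + N(0, quantum_gain·mean_signal·dose_factor) + N(0, electronic_sigma²).

Defaults: 1024×1024 px at 0.125 mm pitch, mean signal 1000 at reference
dose, quantum gain 1, i.e. quantum σ ≈ 32 at standard dose — roughly 3% 
relative noise, a realistic flat-field regime. The dose series
{1.0, 0.2, 0.1} mirrors a standard / 20% / 10% exposure ladder, giving
NNPS ∝ 1/dose for quantum-limited noise. Quantum noise uses the Gaussian
approximation to Poisson statistics (mean counts ≫ 10 everywhere
simulated; exact Poisson sampling via `poisson=True`). One master seed per
spec; frame *i* draws from a stream keyed by (seed, i), so acquisition
sets are reproducible element-wise and share their fixed pattern
bit-exactly.

The anatomy stand-in is a sum of broad Gaussian bumps (default scale 4 mm)
whose spectral energy is ≥ 95% below 0.1× Nyquist, so it occupies the
"structure" band and leaves the noise band clean.

Stand-in denoisers: identity, Gaussian blur, box blur (linear, applied by
circular convolution so the discrete transfer function G(u,v) — the DFT of
the kernel — is exact on the periodogram grid; a deliberate mismatch with
zero-padded spatial filtering at frame edges, irrelevant away from tile
borders), a median filter (the token nonlinear operator, no transfer
function), and a dose-adaptive blur that estimates a frame's relative
noise (std of horizontal first differences / √2, divided by the mean) and
maps it to a blur strength through a threshold table. The default table
(no blur below 4% relative noise, σ = 0.6 px above 4%, σ = 1.2 px above
8%) reproduces the qualitative signature of learning-based denoisers
trained on noisy data: band-mean NPSIF strictly decreasing as dose rises,
equal to 1 at standard dose.

## What the synthetic tests do and do not show

Passing tests demonstrate that the estimator chain is correctly normalised
and unbiased under a stationary, Gaussian, pixel-uncorrelated (or linearly
filtered) noise model with exactly aligned repeat frames. Real detectors
add correlated noise (detector MTF), gain/offset nonuniformity beyond a
static additive pattern, scatter, beam-hardening gradients and possible
frame misregistration; none of these are modelled, and no claim about a
specific physical detector follows from the synthetic results. Absolute
NPS ordinate comparisons with any particular hardware are out of scope.

## Numerical choices

* Polynomial fits use a pseudo-inverse on coordinates normalised to
  [-1, 1] (condition number ~10 at degree 2); design matrices are cached
  per (tile size, degree).
* Problem sizes in the routine test-suite: 256²–512² frames and 16×16
  oracle grids, with Monte-Carlo replicate counts of 20–120 chosen to keep
  statistical tolerances (3 SE, 5% RMS) meaningful; the acceptance script
  runs the full 1024² geometry with 30 pairs / 20 seeds.
* Statistical tolerances use the exponential distribution of periodogram
  bins and Hermitian symmetry (only half the 2D bins are independent).
* Degenerate inputs fail loudly: frames below 256 px per side, anisotropic
  grids fed to the radial average, tiles that do not tile the ROI, empty
  or all-masked curves.

## Known limitations

* The radial average assumes isotropic noise; anisotropic detectors would
  need directional (u/v-axis) profiles, which are not implemented.
* The NPSIF masks near-zero denominators but does not propagate a
  confidence interval per bin; ratio noise at high frequency where the
  processed spectrum is tiny can be large.
* No registration: repeat frames are assumed pixel-aligned.
* Median-filter behaviour is exercised only qualitatively (variance
  decreases); no spectral prediction exists for it.
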