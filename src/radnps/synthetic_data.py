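"""Synthetic flat-panel-detector frames and stand-in denoisers.

The noise model mirrors the three canonical components of digital
radiography detectors:

* quantum noise — photon-statistics noise whose variance scales with dose.
  It is sampled as Gaussian with variance ``quantum_gain * mean_signal *
  dose_factor`` (the Gaussian approximation to Poisson counting noise,
  accurate at the >> 10 mean counts of every regime simulated here; exact
  Poisson sampling is available via ``poisson=True``);
* electronic noise — additive Gaussian readout noise, dose-independent;
* fixed-pattern (structural) noise — a static 2D field injected identically
  into every frame of a set, so pairwise subtraction cancels it exactly.

An optional smooth random field stands in for anatomical background.

Denoisers are deliberately simple operators with known spectra: for the
linear kinds (Gaussian / box blur) filtering is a *circular* convolution,
so the discrete transfer function G(u, v) — the DFT of the kernel — is
exact on the periodogram grid and closed-form predictions like
NPS_out = NPS_in * |G|^2 hold without edge caveats.  The median filter is
the token nonlinear operator and exposes no transfer function.  The
dose-adaptive blur maps the estimated relative noise level of a frame to a
blur strength, emulating a denoiser trained on noisy (low-dose) data whose
benefit shrinks as the input gets cleaner.

Reproducibility: one master seed per spec; the stream for frame ``i`` is
derived from (seed, i), so sets are reproducible element-wise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from .image_io import ImageFrame
from .nps_core import Nps2D, radial_profile
from .residual_noise import AcquisitionSet

__all__ = [
    "SyntheticSpec",
    "DenoiserSpec",
    "gen_flat_frame",
    "gen_flat_set",
    "gen_anatomy_background",
    "apply_denoiser",
    "estimate_noise",
    "transfer_function",
    "theoretical_white_nps",
    "theoretical_linear_npsif",
]

#: Default blur rule for the dose-adaptive denoiser: (relative-noise
#: threshold, Gaussian sigma in px).  The sigma of the largest threshold
#: not exceeding the frame's estimated relative noise is applied.  With the
#: default dose series this leaves standard-dose frames untouched and blurs
#: progressively harder at lower dose.
DEFAULT_ADAPTIVE_RULE: tuple[tuple[float, float], ...] = (
    (0.0, 0.0),
    (0.04, 0.6),
    (0.08, 1.2),
)


@dataclass
class SyntheticSpec:
    """Full parameterisation of a simulated detector frame.

    ``mean_signal`` is the pixel value at reference dose; ``dose_factor``
    scales both the mean and the quantum-noise variance (1.0 = standard
    dose; 0.2 and 0.1 emulate low and ultra-low settings).  Quantum noise
    variance is ``quantum_gain * mean_signal * dose_factor``;
    ``electronic_sigma`` is dose-independent.
    """

    size: int = 1024
    spacing: float = 0.125  # mm / pixel
    mean_signal: float = 1000.0
    dose_factor: float = 1.0
    quantum_gain: float = 1.0
    electronic_sigma: float = 0.0
    fixed_pattern: np.ndarray | None = None
    background: np.ndarray | None = None
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 256:
            raise ValueError(f"size must be >= 256, got {self.size}")
        if self.dose_factor <= 0:
            raise ValueError("dose_factor must be > 0")
        for name in ("spacing", "mean_signal", "quantum_gain", "electronic_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fixed_pattern", "background"):
            arr = getattr(self, name)
            if arr is not None and arr.shape != (self.size, self.size):
                raise ValueError(
                    f"{name} shape {arr.shape} does not match size {self.size}"
                )

    @property
    def quantum_variance(self) -> float:
        return self.quantum_gain * self.mean_signal * self.dose_factor


def gen_flat_frame(
    spec: SyntheticSpec, frame_index: int = 0, label: str = ""
) -> ImageFrame:
    """One simulated frame: mean + background + fixed pattern + noise."""
    rng = np.random.default_rng((spec.seed, frame_index))
    mean = spec.mean_signal * spec.dose_factor
    shape = (spec.size, spec.size)
    if spec.poisson and spec.quantum_gain > 0:
        # counts = signal / gain; pixel value = gain * counts
        lam = np.full(shape, mean / spec.quantum_gain)
        px = spec.quantum_gain * rng.poisson(lam).astype(np.float64)
    else:
        px = np.full(shape, mean)
        if spec.quantum_variance > 0:
            px += rng.normal(0.0, np.sqrt(spec.quantum_variance), shape)
    if spec.electronic_sigma > 0:
        px += rng.normal(0.0, spec.electronic_sigma, shape)
    if spec.background is not None:
        px = px + spec.background
    if spec.fixed_pattern is not None:
        px = px + spec.fixed_pattern
    return ImageFrame(
        px,
        spec.spacing,
        spec.spacing,
        label=label or f"sim(dose={spec.dose_factor}, frame={frame_index})",
        dose_mas=None,
    )


def gen_flat_set(
    spec: SyntheticSpec, n_frames: int = 3, condition: str = ""
) -> AcquisitionSet:
    """Repeat frames from one spec; fixed pattern shared bit-exactly."""
    frames = [gen_flat_frame(spec, frame_index=i) for i in range(n_frames)]
    return AcquisitionSet(frames=frames, condition=condition)


def gen_anatomy_background(
    size: int,
    blobs: int = 25,
    amplitude: float = 200.0,
    smoothness: float = 4.0,
    seed: int = 0,
    spacing: float = 0.125,
) -> np.ndarray:
    """Smooth random field standing in for anatomical structure.

    A sum of ``blobs`` broad 2D Gaussian bumps with spatial scale around
    ``smoothness`` (mm) and peak heights up to ``amplitude``.  The scale
    must exceed 2 pixels so the field's spectral energy stays far below
    the noise band (>= 95% below 0.1x Nyquist for the defaults).
    """
    if smoothness / spacing <= 2:
        raise ValueError(
            f"smoothness {smoothness} mm is <= 2 pixels at {spacing} mm/px"
        )
    rng = np.random.default_rng(seed)
    out = np.zeros((size, size))
    if amplitude == 0 or blobs == 0:
        return out
    coords = np.arange(size) * spacing
    for _ in range(blobs):
        r0, c0 = rng.uniform(0, size * spacing, 2)
        sig = smoothness * rng.uniform(0.7, 1.6)
        amp = amplitude * rng.uniform(0.2, 1.0) * rng.choice([-1, 1])
        out += amp * np.outer(
            np.exp(-0.5 * ((coords - r0) / sig) ** 2),
            np.exp(-0.5 * ((coords - c0) / sig) ** 2),
        )
    return out


def _kernel_grid(d: "DenoiserSpec", size: int) -> np.ndarray:
    """The denoiser kernel wrapped onto a size x size grid, origin at [0,0]."""
    if d.kind == "identity":
        k = np.zeros((size, size))
        k[0, 0] = 1.0
        return k
    if d.kind in ("gaussian_blur", "dose_adaptive_blur"):
        sigma = d.kernel_sigma
        if sigma == 0:
            return _kernel_grid(DenoiserSpec("identity"), size)
        radius = min(int(np.ceil(6 * sigma)), size // 2 - 1)
        off = np.arange(-radius, radius + 1)
        g1 = np.exp(-0.5 * (off / sigma) ** 2)
        g1 /= g1.sum()
        k = np.zeros((size, size))
        idx = off % size
        k[np.ix_(idx, idx)] = np.outer(g1, g1)
        return k
    if d.kind == "box_blur":
        w = d.kernel_size
        if w > size:
            raise ValueError(f"box kernel width {w} exceeds grid {size}")
        off = np.arange(w) - (w - 1) // 2
        k = np.zeros((size, size))
        idx = off % size
        k[np.ix_(idx, idx)] = 1.0 / (w * w)
        return k
    raise ValueError(f"no kernel grid for denoiser kind {d.kind!r}")


@dataclass
class DenoiserSpec:
    """A stand-in noise-reduction operator with a known action.

    kinds: ``identity``, ``gaussian_blur`` (kernel_sigma, px), ``box_blur``
    (kernel_size, px), ``median`` (kernel_size, px; nonlinear — no transfer
    function), ``dose_adaptive_blur`` (adaptive_rule maps estimated relative
    noise to a Gaussian sigma).
    """

    kind: str = "identity"
    kernel_sigma: float = 1.0
    kernel_size: int = 3
    adaptive_rule: tuple[tuple[float, float], ...] = DEFAULT_ADAPTIVE_RULE

    _KINDS = ("identity", "gaussian_blur", "box_blur", "median", "dose_adaptive_blur")
    _LINEAR = ("identity", "gaussian_blur", "box_blur")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(
                f"unknown denoiser kind {self.kind!r}; choose from {self._KINDS}"
            )

    @property
    def is_linear(self) -> bool:
        return self.kind in self._LINEAR


def estimate_noise(frame: ImageFrame) -> tuple[float, float]:
    """(sigma, relative sigma) of a frame's stochastic component.

    Uses the standard deviation of horizontal first differences divided by
    sqrt(2): first differencing suppresses smooth background so the
    estimate tracks pixel-to-pixel noise.
    """
    d = np.diff(frame.pixels, axis=1)
    sigma = float(d.std() / np.sqrt(2.0))
    mean = float(frame.pixels.mean())
    rel = sigma / mean if mean != 0 else np.inf
    return sigma, rel


def _circular_convolve(pixels: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.fft.ifft2(np.fft.fft2(pixels) * np.fft.fft2(kernel)).real


def apply_denoiser(frame: ImageFrame, d: DenoiserSpec) -> ImageFrame:
    """Apply a stand-in denoiser; geometry and metadata are preserved.

    Linear kinds use circular convolution (exact transfer function on the
    periodogram grid); the median filter wraps at the borders for
    consistency.
    """
    if d.kind == "identity":
        out = frame.pixels.copy()
        sigma_used = None
    elif d.kind in ("gaussian_blur", "box_blur"):
        out = _circular_convolve(frame.pixels, _kernel_grid(d, frame.shape[0]))
        sigma_used = None
    elif d.kind == "median":
        out = scipy.ndimage.median_filter(
            frame.pixels, size=d.kernel_size, mode="wrap"
        )
        sigma_used = None
    elif d.kind == "dose_adaptive_blur":
        _, rel = estimate_noise(frame)
        sigma_used = 0.0
        for threshold, sigma in sorted(d.adaptive_rule):
            if rel >= threshold:
                sigma_used = sigma
        if sigma_used > 0:
            eff = DenoiserSpec("gaussian_blur", kernel_sigma=sigma_used)
            out = _circular_convolve(frame.pixels, _kernel_grid(eff, frame.shape[0]))
        else:
            out = frame.pixels.copy()
    else:  # pragma: no cover - guarded in __post_init__
        raise ValueError(f"unknown denoiser kind {d.kind!r}")
    tag = d.kind if sigma_used is None else f"{d.kind}(sigma={sigma_used})"
    return dataclasses.replace(frame, pixels=out, label=f"{frame.label}+{tag}")


def transfer_function(d: DenoiserSpec, size: int) -> np.ndarray:
    """|G(u, v)| of a linear denoiser on a size x size DFT grid (DC at [0,0])."""
    if not d.is_linear:
        raise ValueError(f"denoiser kind {d.kind!r} is nonlinear; no transfer function")
    return np.abs(np.fft.fft2(_kernel_grid(d, size)))


def theoretical_white_nps(sigma: float, spacing: float) -> float:
    """Flat radial NPS level of white noise: sigma^2 * spacing^2 (isotropic)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return sigma**2 * spacing**2


def theoretical_linear_npsif(
    d: DenoiserSpec,
    freqs: np.ndarray,
    grid_size: int = 256,
    spacing: float = 0.125,
) -> np.ndarray:
    """Exact NPSIF of a linear denoiser on white noise: 1 / <|G|^2>_radial.

    |G|^2 is evaluated on the same DFT grid the NPS pipeline uses and
    radially averaged with the same binning; the result is returned at the
    requested frequencies (which must coincide with radial bin centres).
    """
    g2 = transfer_function(d, grid_size) ** 2
    prof = radial_profile(
        Nps2D(
            power=g2,
            freq_step_row=1.0 / (grid_size * spacing),
            freq_step_col=1.0 / (grid_size * spacing),
        ),
        exclude_dc=True,
    )
    freqs = np.asarray(freqs, dtype=float)
    idx = np.searchsorted(prof.freq, freqs)
    idx = np.clip(idx, 0, len(prof.freq) - 1)
    left = np.clip(idx - 1, 0, len(prof.freq) - 1)
    idx = np.where(
        np.abs(prof.freq[left] - freqs) < np.abs(prof.freq[idx] - freqs), left, idx
    )
    if not np.allclose(prof.freq[idx], freqs, rtol=1e-6, atol=1e-9):
        raise ValueError("requested frequencies do not match radial bin centres")
    return 1.0 / prof.value[idx]
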