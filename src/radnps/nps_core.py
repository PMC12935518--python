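"""Noise power spectrum estimation from tiled, detrended periodograms.

The procedure: crop a square analysis ROI (default 1024x1024) from the
image, subdivide it into local ROIs (default 256x256, non-overlapping),
subtract a least-squares 2D polynomial trend from each local ROI, take the
2D periodogram of each fluctuation component, average the periodograms, and
reduce the averaged 2D spectrum to a 1D curve by radial frequency
averaging.

Normalisation follows the standard flat-panel convention

    NPS(u, v) = (dx * dy / (Nx * Ny)) * |DFT2(fluctuation)|^2,

which gives units of (pixel value)^2 * mm^2 and makes white noise of pixel
variance sigma^2 come out at the flat level sigma^2 * dx * dy.  No window
or taper is applied before the transform.  The DC bin of the 2D spectrum
sits at index (0, 0) (unshifted DFT layout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import ImageFrame, require_analysis_size

__all__ = [
    "RoiStack",
    "Nps2D",
    "RadialNps",
    "NpsConfig",
    "extract_analysis_roi",
    "tile_local_rois",
    "detrend_tile",
    "tile_periodogram",
    "average_periodograms",
    "radial_profile",
    "nps_pipeline",
]


@dataclass
class RoiStack:
    """Square local ROIs cut from an analysis ROI, with their origins."""

    parent: ImageFrame
    tiles: list[np.ndarray]
    offsets: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.tiles:
            raise ValueError("RoiStack needs at least one tile")
        s = self.tiles[0].shape
        if s[0] != s[1] or any(t.shape != s for t in self.tiles):
            raise ValueError("all tiles must share one square size")

    @property
    def tile_size(self) -> int:
        return self.tiles[0].shape[0]


@dataclass
class Nps2D:
    """2D noise power spectrum on the unshifted DFT grid (DC at [0, 0]).

    ``power`` has units (pixel value)^2 * mm^2; ``freq_step_*`` are the grid
    steps 1/(S*dx) in cycles/mm; ``n_averaged`` counts the local ROIs that
    contributed.
    """

    power: np.ndarray
    freq_step_row: float
    freq_step_col: float
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        if self.power.ndim != 2:
            raise ValueError("power must be 2D")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if not (self.freq_step_row > 0 and self.freq_step_col > 0):
            raise ValueError("frequency steps must be positive")
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")


@dataclass
class RadialNps:
    """1D radially averaged NPS: value (pixel value)^2 mm^2 vs cycles/mm."""

    freq: np.ndarray
    value: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        self.value = np.asarray(self.value, dtype=np.float64)
        self.count = np.asarray(self.count, dtype=np.int64)
        if not (self.freq.shape == self.value.shape == self.count.shape):
            raise ValueError("freq, value, count must have equal length")
        if self.freq.size and (
            self.freq[0] < 0 or np.any(np.diff(self.freq) <= 0)
        ):
            raise ValueError("freq must be non-negative and strictly increasing")
        if np.any(self.count < 1):
            raise ValueError("every reported bin needs at least one grid point")

    def __len__(self) -> int:
        return self.freq.size


@dataclass
class NpsConfig:
    """Settings for the full NPS pipeline (see module docstring)."""

    roi_size: int = 1024
    tile_size: int = 256
    overlap: float = 0.0  # 0 = non-overlapping grid, 0.5 = half-stride grid
    detrend_order: int = 2
    exclude_dc: bool = True
    exclude_axes: bool = False


def extract_analysis_roi(
    frame: ImageFrame, center_row: int, center_col: int, size: int = 1024
) -> ImageFrame:
    """Crop a size x size square centred at (center_row, center_col).

    Raises with the offending extents when the crop exceeds the frame.
    """
    r0 = int(center_row) - size // 2
    c0 = int(center_col) - size // 2
    r1, c1 = r0 + size, c0 + size
    nr, nc = frame.shape
    if r0 < 0 or c0 < 0 or r1 > nr or c1 > nc:
        raise ValueError(
            f"analysis ROI rows [{r0}, {r1}) cols [{c0}, {c1}) exceeds "
            f"frame bounds {frame.shape}"
        )
    return frame.with_pixels(frame.pixels[r0:r1, c0:c1])


def tile_local_rois(
    roi: ImageFrame, tile_size: int = 256, overlap: float = 0.0
) -> RoiStack:
    """Subdivide the analysis ROI into square local ROIs.

    ``overlap`` 0 gives a non-overlapping grid (tile size must divide the
    ROI); 0.5 gives a half-stride grid (7x7 = 49 tiles for 1024/256).
    """
    if overlap not in (0, 0.0, 0.5):
        raise ValueError(f"overlap must be 0 or 0.5, got {overlap}")
    nr, nc = roi.shape
    if tile_size > nr or tile_size > nc:
        raise ValueError(f"tile size {tile_size} exceeds ROI shape {roi.shape}")
    stride = tile_size if overlap == 0 else tile_size // 2
    for n in (nr, nc):
        if (n - tile_size) % stride != 0:
            raise ValueError(
                f"ROI side {n} is not covered by stride-{stride} tiles of "
                f"size {tile_size}"
            )
    tiles, offsets = [], []
    for r in range(0, nr - tile_size + 1, stride):
        for c in range(0, nc - tile_size + 1, stride):
            tiles.append(roi.pixels[r : r + tile_size, c : c + tile_size])
            offsets.append((r, c))
    return RoiStack(parent=roi, tiles=tiles, offsets=offsets)


# Cached polynomial design matrices and their pseudo-inverses, keyed by
# (tile side, order).  Coordinates are normalised to [-1, 1] per axis for
# conditioning; the fitted residual is invariant to that affine choice.
_BASIS_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _poly_basis(size: int, order: int) -> tuple[np.ndarray, np.ndarray]:
    key = (size, order)
    if key not in _BASIS_CACHE:
        t = np.linspace(-1.0, 1.0, size)
        y, x = np.meshgrid(t, t, indexing="ij")
        cols = [np.ones(size * size)]
        if order >= 1:
            cols += [x.ravel(), y.ravel()]
        if order >= 2:
            cols += [(x * x).ravel(), (x * y).ravel(), (y * y).ravel()]
        basis = np.column_stack(cols)
        _BASIS_CACHE[key] = (basis, np.linalg.pinv(basis))
    return _BASIS_CACHE[key]


def detrend_tile(tile: np.ndarray, order: int = 2) -> np.ndarray:
    """Subtract the least-squares 2D polynomial surface of total degree <= order.

    Order 2 uses the six terms 1, x, y, x^2, xy, y^2.  The returned
    fluctuation component has zero mean and is orthogonal to every basis
    term (to numerical precision).
    """
    tile = np.asarray(tile, dtype=np.float64)
    if tile.ndim != 2 or tile.shape[0] != tile.shape[1]:
        raise ValueError(f"tile must be square 2D, got shape {tile.shape}")
    if order not in (0, 1, 2):
        raise ValueError(f"detrend order must be in {{0, 1, 2}}, got {order}")
    basis, pinv = _poly_basis(tile.shape[0], order)
    flat = tile.ravel()
    residual = flat - basis @ (pinv @ flat)
    return residual.reshape(tile.shape)


def detrend_suppression(size: int, order: int = 2) -> np.ndarray:
    """Expected white-noise power suppression of the polynomial detrend.

    Subtracting the least-squares polynomial surface removes the component
    of every Fourier mode lying in the polynomial span.  For white noise
    the expected periodogram after detrending is the flat level times

        D(u, v) = 1 - sum_j |q_j_hat(u, v)|^2 / N,

    with q_j an orthonormal basis of the polynomial span and N = size^2.
    D is ~0 at DC, noticeably below 1 in the few lowest-frequency bins
    (about 0.56 at the first radial bin for order 2), and ~1 elsewhere.
    Returned on the unshifted DFT grid.
    """
    basis, _ = _poly_basis(size, order)
    q, _ = np.linalg.qr(basis)
    d = np.ones((size, size))
    for j in range(q.shape[1]):
        d -= np.abs(np.fft.fft2(q[:, j].reshape(size, size))) ** 2 / (size * size)
    return np.clip(d, 0.0, None)


def tile_periodogram(
    fluct: np.ndarray, spacing_row: float, spacing_col: float
) -> Nps2D:
    """2D periodogram of one fluctuation tile, physically normalised.

    The caller is responsible for detrending; no taper is applied.
    """
    fluct = np.asarray(fluct, dtype=np.float64)
    if spacing_row <= 0 or spacing_col <= 0:
        raise ValueError("pixel spacing must be positive")
    nr, nc = fluct.shape
    power = (spacing_row * spacing_col / (nr * nc)) * np.abs(np.fft.fft2(fluct)) ** 2
    return Nps2D(
        power=power,
        freq_step_row=1.0 / (nr * spacing_row),
        freq_step_col=1.0 / (nc * spacing_col),
        n_averaged=1,
    )


def average_periodograms(spectra: list[Nps2D]) -> Nps2D:
    """Element-wise mean of periodograms sharing one frequency grid."""
    if not spectra:
        raise ValueError("nothing to average")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.power.shape != ref.power.shape:
            raise ValueError(
                f"grid size mismatch: {s.power.shape} vs {ref.power.shape}"
            )
        if not (
            np.isclose(s.freq_step_row, ref.freq_step_row, rtol=1e-9)
            and np.isclose(s.freq_step_col, ref.freq_step_col, rtol=1e-9)
        ):
            raise ValueError("frequency step mismatch between periodograms")
    mean = np.mean([s.power for s in spectra], axis=0)
    return Nps2D(
        power=mean,
        freq_step_row=ref.freq_step_row,
        freq_step_col=ref.freq_step_col,
        n_averaged=sum(s.n_averaged for s in spectra),
    )


def radial_profile(
    nps: Nps2D, exclude_dc: bool = True, exclude_axes: bool = False
) -> RadialNps:
    """Reduce a 2D NPS to 1D by averaging over annuli of constant |f|.

    Bins of width du (the grid frequency step) are centred at k*du; each 2D
    grid point at radius r = sqrt(u^2 + v^2) goes to the nearest bin centre.
    Corner points with r beyond the axis Nyquist are discarded, so the 1D
    axis ends at Nyquist.  The DC point is dropped by default (detrending
    drives it to zero, and it would distort the first bin); ``exclude_axes``
    additionally drops the two frequency-axis lines.

    Requires an isotropic grid (equal row/col frequency steps).
    """
    if not np.isclose(nps.freq_step_row, nps.freq_step_col, rtol=1e-9):
        raise ValueError(
            f"radial averaging needs isotropic frequency steps, got "
            f"({nps.freq_step_row}, {nps.freq_step_col}) cycles/mm"
        )
    du = nps.freq_step_row
    nr, nc = nps.power.shape
    fr = np.fft.fftfreq(nr, d=1.0 / (nr * du))
    fc = np.fft.fftfreq(nc, d=1.0 / (nc * du))
    rad = np.hypot(fr[:, None], fc[None, :])
    nyquist = du * (min(nr, nc) // 2)

    keep = rad <= nyquist * (1 + 1e-12)
    if exclude_axes:
        keep &= (fr[:, None] != 0) & (fc[None, :] != 0)
    elif exclude_dc:
        keep[0, 0] = False

    k = np.rint(rad[keep] / du).astype(np.int64)
    vals = nps.power[keep]
    nbins = int(min(nr, nc) // 2) + 1
    sums = np.bincount(k, weights=vals, minlength=nbins)
    counts = np.bincount(k, minlength=nbins)

    k0 = 1 if exclude_dc or exclude_axes else 0
    idx = np.arange(k0, nbins)
    idx = idx[counts[idx] > 0]
    return RadialNps(
        freq=idx * du,
        value=sums[idx] / counts[idx],
        count=counts[idx],
    )


def nps_pipeline(
    frame: ImageFrame,
    center: tuple[int, int] | None = None,
    config: NpsConfig | None = None,
) -> RadialNps:
    """Full measurement: crop -> tile -> detrend -> periodogram -> average -> radial.

    ``center`` defaults to the frame centre.
    """
    cfg = config or NpsConfig()
    require_analysis_size(frame)
    if center is None:
        center = (frame.shape[0] // 2, frame.shape[1] // 2)
    roi = extract_analysis_roi(frame, center[0], center[1], size=cfg.roi_size)
    stack = tile_local_rois(roi, tile_size=cfg.tile_size, overlap=cfg.overlap)
    spectra = [
        tile_periodogram(
            detrend_tile(t, order=cfg.detrend_order),
            roi.spacing_row,
            roi.spacing_col,
        )
        for t in stack.tiles
    ]
    return radial_profile(
        average_periodograms(spectra),
        exclude_dc=cfg.exclude_dc,
        exclude_axes=cfg.exclude_axes,
    )
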