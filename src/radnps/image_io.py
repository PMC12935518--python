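"""Reading and writing radiographic images and spectral tables.

Pixel values are treated as linear detector output throughout: a DICOM
rescale (slope/intercept) is applied when present, but no value-of-interest
LUT or display windowing is ever honoured.  Row/column pixel spacings are
kept distinct; isotropy is asserted only where the radial frequency method
requires it.

Coordinate convention: row-major, 0-based pixel indices, with (0, 0) the
centre of the top-left pixel.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pydicom
import tifffile

__all__ = [
    "ImageFrame",
    "read_dicom",
    "read_raster",
    "write_raster",
    "write_table",
    "read_radial_table",
]

#: Minimum side length required before any NPS analysis is meaningful
#: (one full local ROI at the default tile size).
MIN_ANALYSIS_SIZE = 256


@dataclass
class ImageFrame:
    """A single radiographic image with its physical pixel geometry.

    Parameters
    ----------
    pixels
        2D array of detector output values (arbitrary linear units).
    spacing_row, spacing_col
        Physical pixel pitch in mm along rows and columns; strictly positive.
    label
        Free-text condition tag (processing name, dose level, ...).
    dose_mas
        Optional tube-current-time product in mAs (> 0 when given).
    """

    pixels: np.ndarray
    spacing_row: float
    spacing_col: float
    label: str = ""
    dose_mas: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if not (self.spacing_row > 0 and self.spacing_col > 0):
            raise ValueError(
                f"pixel spacing must be strictly positive, got "
                f"({self.spacing_row}, {self.spacing_col})"
            )
        if self.dose_mas is not None and not self.dose_mas > 0:
            raise ValueError(f"dose_mas must be > 0, got {self.dose_mas}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, label: str | None = None) -> "ImageFrame":
        """Copy of this frame with new pixel data (geometry preserved)."""
        return dataclasses.replace(
            self, pixels=pixels, label=self.label if label is None else label
        )


def require_analysis_size(frame: ImageFrame) -> None:
    """Raise if the frame is too small for any NPS analysis (< 256 per side)."""
    r, c = frame.shape
    if r < MIN_ANALYSIS_SIZE or c < MIN_ANALYSIS_SIZE:
        raise ValueError(
            f"frame of shape {frame.shape} is below the minimum "
            f"{MIN_ANALYSIS_SIZE}x{MIN_ANALYSIS_SIZE} required for NPS analysis"
        )


def read_dicom(
    path: str | os.PathLike,
    spacing_override: tuple[float, float] | None = None,
    label: str | None = None,
) -> ImageFrame:
    """Read a single-frame monochrome DICOM image.

    The linear rescale (RescaleSlope/RescaleIntercept) is applied when
    present.  Pixel spacing is taken from PixelSpacing (or
    ImagerPixelSpacing) in mm as (row, column); ``spacing_override``
    replaces it and is required when the file carries no spacing.

    Raises
    ------
    ValueError
        For compressed transfer syntaxes (named in the message), multi-frame
        or colour images, or missing pixel spacing with no override.
    """
    ds = pydicom.dcmread(path)
    syntax = getattr(ds.file_meta, "TransferSyntaxUID", None)
    if syntax is not None and syntax.is_compressed:
        raise ValueError(
            f"compressed DICOM transfer syntax not supported: {syntax.name} ({syntax})"
        )
    if int(getattr(ds, "NumberOfFrames", 1)) != 1:
        raise ValueError("multi-frame DICOM is not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise ValueError("only monochrome (SamplesPerPixel=1) DICOM is supported")

    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if slope != 1.0 or intercept != 0.0:
        arr = slope * arr + intercept

    if spacing_override is not None:
        spacing_row, spacing_col = map(float, spacing_override)
    else:
        spacing = getattr(ds, "PixelSpacing", None) or getattr(
            ds, "ImagerPixelSpacing", None
        )
        if spacing is None:
            raise ValueError(
                f"{path}: no PixelSpacing/ImagerPixelSpacing metadata; "
                "supply spacing_override=(row_mm, col_mm)"
            )
        spacing_row, spacing_col = float(spacing[0]), float(spacing[1])

    if label is None:
        label = str(getattr(ds, "SeriesDescription", ""))
    return ImageFrame(arr, spacing_row, spacing_col, label=label)


def read_raster(
    path: str | os.PathLike,
    spacing_row: float,
    spacing_col: float,
    label: str = "",
) -> ImageFrame:
    """Read a 16-bit or float grayscale TIFF/PNG with user-supplied spacing (mm)."""
    arr = iio.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected single-channel grayscale image, got shape {arr.shape}"
        )
    return ImageFrame(arr.astype(np.float64), spacing_row, spacing_col, label=label)


def write_raster(frame: ImageFrame, path: str | os.PathLike) -> None:
    """Write a frame as 16-bit grayscale when lossless, else float32 TIFF.

    Integer-valued pixels in [0, 65535] are stored as uint16 so that a
    write/read round trip is bit-exact for 16-bit data.
    """
    px = frame.pixels
    integral = np.all(px == np.rint(px)) and px.min() >= 0 and px.max() <= 65535
    suffix = os.fspath(path).lower()
    if integral:
        data = px.astype(np.uint16)
    elif suffix.endswith(".png"):
        raise ValueError("PNG output supports only 16-bit integer data in [0, 65535]")
    else:
        data = px.astype(np.float32)
    if suffix.endswith((".tif", ".tiff")):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_table(curve, path: str | os.PathLike) -> None:
    """Write a RadialNps or NpsifCurve as CSV (frequencies in cycles/mm).

    Values are printed with 12 significant digits so a read-back reproduces
    them to better than 1e-9 relative.  Masked NPSIF bins are written as
    empty cells with ``masked = 1``.
    """
    freq = np.asarray(getattr(curve, "freq", ()), dtype=float)
    if freq.size == 0:
        raise ValueError("refusing to write an empty curve")
    if hasattr(curve, "mask"):  # NPSIF curve
        df = pd.DataFrame(
            {
                "freq_cycles_per_mm": freq,
                "npsif": np.where(curve.mask, curve.value, np.nan),
                "masked": (~curve.mask).astype(int),
            }
        )
    elif hasattr(curve, "count"):  # radial NPS
        df = pd.DataFrame(
            {
                "freq_cycles_per_mm": freq,
                "nps": curve.value,
                "count": curve.count,
            }
        )
    else:
        raise TypeError(f"unsupported curve type: {type(curve).__name__}")
    df.to_csv(path, index=False, float_format="%.12g")


def read_radial_table(path: str | os.PathLike):
    """Read back a radial-NPS CSV written by :func:`write_table`."""
    from .nps_core import RadialNps  # local import to avoid a cycle

    df = pd.read_csv(path)
    if "freq_cycles_per_mm" not in df or "nps" not in df:
        raise ValueError(f"{path}: not a radial NPS table")
    count = (
        df["count"].to_numpy(dtype=np.int64)
        if "count" in df
        else np.ones(len(df), dtype=np.int64)
    )
    return RadialNps(
        freq=df["freq_cycles_per_mm"].to_numpy(dtype=float),
        value=df["nps"].to_numpy(dtype=float),
        count=count,
    )
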