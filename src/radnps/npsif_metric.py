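"""NPS improvement factor: NPSIF(u) = NPS_without(u) / NPS_with(u).

A value above 1 at a spatial frequency means the processing reduced noise
power there; below 1 means it increased it.  The ratio is taken on the 1D
radial spectra.  Because a ratio is ill-behaved where the denominator
spectrum carries almost no power, such bins are masked rather than reported
as (near-)infinite numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nps_core import RadialNps

__all__ = ["NpsifCurve", "compute_npsif", "band_mean"]


@dataclass
class NpsifCurve:
    """Frequency-wise NPS ratio with a per-bin validity mask.

    ``value`` is only meaningful where ``mask`` is True; masked entries are
    NaN.  ``label_minus``/``label_plus`` identify the without- and
    with-processing inputs.
    """

    freq: np.ndarray
    value: np.ndarray
    mask: np.ndarray
    label_minus: str = ""
    label_plus: str = ""

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        self.value = np.asarray(self.value, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.freq.shape == self.value.shape == self.mask.shape):
            raise ValueError("freq, value, mask must have equal length")
        if self.freq.size and np.any(np.diff(self.freq) <= 0):
            raise ValueError("freq must be strictly increasing")
        if np.any(self.value[self.mask] <= 0):
            raise ValueError("unmasked NPSIF values must be positive")

    def __len__(self) -> int:
        return self.freq.size


def compute_npsif(
    nps_minus: RadialNps,
    nps_plus: RadialNps,
    guard: float = 1e-12,
) -> NpsifCurve:
    """Ratio of the without-processing to the with-processing radial NPS.

    The two spectra must share one frequency grid (bin centres equal to
    1e-9 relative).  Bins where the denominator falls below
    ``guard * max(denominator)`` are masked.
    """
    if len(nps_minus) != len(nps_plus):
        raise ValueError(
            f"grid length mismatch: {len(nps_minus)} vs {len(nps_plus)} bins"
        )
    scale = max(nps_minus.freq.max(), nps_plus.freq.max(), 1.0)
    bad = ~np.isclose(nps_minus.freq, nps_plus.freq, rtol=1e-9, atol=1e-9 * scale)
    if np.any(bad):
        i = int(np.argmax(bad))
        raise ValueError(
            f"frequency grids differ first at bin {i}: "
            f"{nps_minus.freq[i]} vs {nps_plus.freq[i]} cycles/mm"
        )
    denom = nps_plus.value
    dmax = denom.max()
    if not dmax > 0:
        raise ValueError("denominator spectrum is zero everywhere; no valid bins")
    mask = denom >= guard * dmax
    value = np.full_like(denom, np.nan)
    value[mask] = nps_minus.value[mask] / denom[mask]
    return NpsifCurve(
        freq=nps_minus.freq.copy(),
        value=value,
        mask=mask,
    )


def band_mean(curve: NpsifCurve, f_lo: float, f_hi: float) -> float:
    """Arithmetic mean of unmasked NPSIF values with f_lo <= freq <= f_hi."""
    if not f_lo < f_hi:
        raise ValueError(f"need f_lo < f_hi, got [{f_lo}, {f_hi}]")
    sel = (curve.freq >= f_lo) & (curve.freq <= f_hi) & curve.mask
    if not sel.any():
        raise ValueError(
            f"no unmasked bins in band [{f_lo}, {f_hi}] cycles/mm"
        )
    return float(curve.value[sel].mean())
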