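"""Welch PSD estimation and three-band power-ratio summarization.

The power spectral density of each parcel mean time series is estimated
with Welch's overlapped segment averaging (Hann taper, 200 s windows, 50%
overlap by default).  The low-frequency range 0.01-0.08 Hz is divided into
three equal sub-bands and each sub-band's share of the total in-band power
is reported; the ratios are scale-free, so only relative spectral shape
feeds group analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass
class PsdEstimate:
    frequencies_hz: np.ndarray
    power: np.ndarray
    window_seconds: float
    overlap_fraction: float
    n_segments: int

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies_hz.shape != self.power.shape:
            raise ValueError("frequency and power grids must align")
        if (self.power < 0).any():
            raise ValueError("power densities must be non-negative")
        if (np.diff(self.frequencies_hz) <= 0).any():
            raise ValueError("frequency grid must be strictly ascending")


@dataclass
class BandRatios:
    """Fractions of 0.01-0.08 Hz power in its three equal sub-bands."""

    low: float
    medium: float
    high: float

    def __post_init__(self) -> None:
        for name in ("low", "medium", "high"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} ratio {val} outside [0, 1]")
        if abs(self.low + self.medium + self.high - 1.0) > 1e-10:
            raise ValueError("band ratios must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.low, self.medium, self.high)


def welch_psd(
    series: np.ndarray,
    tr_seconds: float,
    window_seconds: float = 200.0,
    overlap_fraction: float = 0.5,
) -> PsdEstimate:
    """Welch PSD of one time series.

    Segments of ``L = round(window_seconds / tr)`` samples advance by
    ``L * (1 - overlap_fraction)``; each segment is mean-removed (linear
    detrending is an upstream stage), Hann-tapered, and its periodogram
    averaged with density normalization.
    """
    series = np.asarray(series, dtype=float).ravel()
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if not (0.0 <= overlap_fraction < 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1)")
    nperseg = int(round(window_seconds / tr_seconds))
    if abs(nperseg * tr_seconds - window_seconds) > 0.5 * tr_seconds:
        raise ValueError("window_seconds must be a multiple of TR (within rounding)")
    if nperseg < 2:
        raise ValueError("window too short: fewer than 2 samples")
    if series.size < nperseg:
        raise ValueError(
            f"series of {series.size} samples shorter than one window "
            f"({nperseg} samples)"
        )
    noverlap = int(round(nperseg * overlap_fraction))
    hop = nperseg - noverlap
    n_segments = (series.size - nperseg) // hop + 1
    freqs, power = signal.welch(
        series, fs=1.0 / tr_seconds, window="hann", nperseg=nperseg,
        noverlap=noverlap, detrend="constant", scaling="density",
    )
    return PsdEstimate(freqs, power, window_seconds, overlap_fraction, n_segments)


def band_ratios(
    psd: PsdEstimate, band_low: float = 0.01, band_high: float = 0.08
) -> BandRatios:
    """Split ``[band_low, band_high]`` into three equal sub-bands by power.

    A frequency bin belongs to the sub-band containing its center; sub-band
    edges are left-closed, with the last band right-closed.  Each ratio is
    that sub-band's power sum over the total in-band power sum.
    """
    if band_low >= band_high:
        raise ValueError("band_low must be below band_high")
    f = psd.frequencies_hz
    if f[0] > band_low or f[-1] < band_high:
        raise ValueError(
            f"PSD grid [{f[0]:g}, {f[-1]:g}] Hz does not cover the band "
            f"[{band_low:g}, {band_high:g}] Hz"
        )
    edges = np.linspace(band_low, band_high, 4)
    in_band = (f >= band_low) & (f <= band_high)
    total = psd.power[in_band].sum()
    if total <= 0:
        raise ValueError("total band power is zero; ratios undefined")
    sums = []
    for i in range(3):
        lo, hi = edges[i], edges[i + 1]
        if i < 2:
            sel = (f >= lo) & (f < hi)
        else:
            sel = (f >= lo) & (f <= hi)
        sums.append(psd.power[sel].sum())
    low, medium, high = (s / total for s in sums)
    return BandRatios(low, medium, high)
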