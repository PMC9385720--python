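"""Post-normalization functional preprocessing.

Operates on 4D resting-state volumes that are assumed to be already
slice-time/motion corrected and spatially normalized (that part of the
pipeline is upstream and out of scope).  Provides voxelwise linear
detrending, zero-phase temporal band-pass filtering, isotropic Gaussian
smoothing, and thresholding of a WM tissue-probability map into a tight
binary mask.

The canonical stage order is smooth -> detrend -> band-pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class Volume4D:
    """A 4D signal grid (x, y, z, t) with acquisition geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        Real-valued voxel time series.
    tr_seconds : float
        Repetition time (sampling interval) in seconds.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    """

    data: np.ndarray
    tr_seconds: float = 2.0
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"Volume4D requires a 4D array, got {self.data.ndim}D"
            )
        if self.data.shape[-1] < 4:
            raise ValueError(
                f"Volume4D requires >= 4 timepoints, got {self.data.shape[-1]}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume4D data must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds

    def like(self, data: np.ndarray) -> "Volume4D":
        """New volume with the same geometry and different data."""
        return Volume4D(data, self.tr_seconds, self.voxel_size_mm)


@dataclass
class BinaryMask:
    """A boolean voxel mask with the threshold that produced it."""

    mask: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def detrend_linear(v: Volume4D) -> Volume4D:
    """Remove the voxelwise least-squares linear trend (intercept + slope).

    Eliminates slow scanner drift: after detrending every voxel series has
    zero mean and zero least-squares slope.
    """
    if v.n_timepoints < 3:
        raise ValueError("detrend_linear requires >= 3 timepoints")
    out = signal.detrend(v.data, axis=-1, type="linear")
    return v.like(out)


def bandpass(v: Volume4D, low_hz: float = 0.01, high_hz: float = 0.1) -> Volume4D:
    """Zero-phase temporal band-pass filter.

    A 4th-order Butterworth band-pass applied forward and backward
    (``sosfiltfilt``), so pass-band components are not shifted in time --
    a requirement for downstream temporal correlations.  DC is rejected.
    """
    nyq = v.nyquist_hz
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq:g} Hz at TR {v.tr_seconds:g} s)"
        )
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass",
                        fs=1.0 / v.tr_seconds, output="sos")
    out = signal.sosfiltfilt(sos, v.data, axis=-1)
    return v.like(out)


def smooth_gaussian(v: Volume4D, fwhm_mm: float = 4.0) -> Volume4D:
    """Spatial smoothing with an isotropic Gaussian kernel.

    Each time frame is convolved with a Gaussian of the given full-width at
    half-maximum (sigma = FWHM / 2.3548, converted from mm to voxels).
    Boundaries use reflective padding, which conserves the spatial sum of
    each frame.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return v.like(v.data.copy())
    sigma_vox = fwhm_mm / FWHM_TO_SIGMA / v.voxel_size_mm
    out = ndimage.gaussian_filter(
        v.data, sigma=(sigma_vox, sigma_vox, sigma_vox, 0.0), mode="reflect"
    )
    return v.like(out)


def threshold_wm_mask(prob_map: np.ndarray, threshold: float = 0.95) -> BinaryMask:
    """Threshold a WM tissue-probability map into a tight binary mask.

    The default 0.95 cut keeps only near-pure WM voxels to avoid partial
    volume contamination from adjacent gray matter.  The rule is inclusive:
    a voxel at exactly the threshold is retained.  An empty mask triggers a
    warning (downstream ROI extraction raises if a bundle loses all voxels).
    """
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    mask = prob_map >= threshold
    if not mask.any():
        warnings.warn(
            f"WM mask is empty at threshold {threshold:g}", stacklevel=2
        )
    return BinaryMask(mask, threshold=threshold)
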