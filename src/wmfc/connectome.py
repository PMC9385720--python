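"""ROI mean time series and the WM-GM correlation connectome.

Mean BOLD time series are extracted per parcel -- WM bundles restricted to
the subject's tight WM mask, GM regions over all their voxels -- and the
bundle x region matrix of Pearson correlation coefficients (CC) is reduced
to the bundle-level mean correlation (mCC): a bundle's CC averaged over all
its GM correlations, with the region-level column average as companion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import BinaryMask, Volume4D
from .synthetic import AtlasSpec


@dataclass
class RoiTimeSeriesMatrix:
    """Parcel-by-timepoint mean signals plus voxel bookkeeping."""

    parcel_labels: list[int]
    parcel_names: list[str]
    series: np.ndarray  # (n_parcels, n_timepoints)
    n_voxels_used: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.atleast_2d(np.asarray(self.series, dtype=float))
        self.n_voxels_used = np.asarray(self.n_voxels_used, dtype=int)
        if self.series.shape[0] != len(self.parcel_labels):
            raise ValueError("one series row per parcel required")
        if (self.n_voxels_used < 1).any():
            raise ValueError("every retained parcel needs >= 1 voxel")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


@dataclass
class WmGmConnectome:
    """WM-bundle x GM-region Pearson correlation matrix."""

    cc: np.ndarray
    bundle_labels: list[int]
    region_labels: list[int]

    def __post_init__(self) -> None:
        self.cc = np.asarray(self.cc, dtype=float)
        if self.cc.shape != (len(self.bundle_labels), len(self.region_labels)):
            raise ValueError("cc matrix shape must match label lists")
        finite = self.cc[np.isfinite(self.cc)]
        if finite.size and (np.abs(finite) > 1.0 + 1e-12).any():
            raise ValueError("correlation entries must lie in [-1, 1]")


@dataclass
class BundleMcc:
    """Row (bundle) and column (region) means of a connectome."""

    bundle_mcc: np.ndarray
    region_mcc: np.ndarray
    bundle_labels: list[int]
    region_labels: list[int]


def extract_roi_means(
    v: Volume4D,
    atlas: AtlasSpec,
    wm_mask: BinaryMask | None = None,
) -> tuple[RoiTimeSeriesMatrix, RoiTimeSeriesMatrix]:
    """Mean time series per WM bundle and GM region.

    WM bundles average only voxels in (parcel intersect ``wm_mask``); a
    bundle whose intersection is empty raises (the mask is over-tight for
    that bundle).  GM regions average all their voxels.

    Returns ``(wm_ts, gm_ts)``.
    """
    if atlas.grid_dims != v.grid_dims:
        raise ValueError(
            f"atlas grid {atlas.grid_dims} does not match volume grid "
            f"{v.grid_dims}"
        )
    if wm_mask is not None and wm_mask.mask.shape != v.grid_dims:
        raise ValueError("WM mask grid does not match volume grid")

    def mean_series(parcels, restrict):
        rows, counts = [], []
        for p in parcels:
            if restrict is not None:
                keep = restrict[p.index]
                voxels = p.voxels[keep]
                if voxels.shape[0] == 0:
                    raise ValueError(
                        f"WM bundle {p.name} (label {p.label}) has no voxels "
                        f"inside the WM mask (threshold "
                        f"{wm_mask.threshold}); mask is too tight"
                    )
            else:
                voxels = p.voxels
            rows.append(v.data[tuple(voxels.T)].mean(axis=0))
            counts.append(voxels.shape[0])
        return rows, counts

    wm_rows, wm_counts = mean_series(
        atlas.wm_parcels, None if wm_mask is None else wm_mask.mask
    )
    gm_rows, gm_counts = mean_series(atlas.gm_parcels, None)
    wm_ts = RoiTimeSeriesMatrix(
        [p.label for p in atlas.wm_parcels],
        [p.name for p in atlas.wm_parcels],
        np.array(wm_rows), np.array(wm_counts),
    )
    gm_ts = RoiTimeSeriesMatrix(
        [p.label for p in atlas.gm_parcels],
        [p.name for p in atlas.gm_parcels],
        np.array(gm_rows), np.array(gm_counts),
    )
    return wm_ts, gm_ts


def pairwise_cc(
    wm_ts: RoiTimeSeriesMatrix, gm_ts: RoiTimeSeriesMatrix
) -> WmGmConnectome:
    """Pearson correlation of every WM bundle with every GM region.

    Zero-variance series cannot be correlated; their entries are set to NaN
    with a warning and are excluded from downstream mCC averaging (injecting
    artificial zeros would bias the bundle means).
    """
    if wm_ts.n_timepoints != gm_ts.n_timepoints:
        raise ValueError("WM and GM series must share the timepoint count")
    if wm_ts.n_timepoints < 3:
        raise ValueError("correlation requires >= 3 timepoints")

    def zscore(mat: RoiTimeSeriesMatrix) -> tuple[np.ndarray, np.ndarray]:
        x = mat.series - mat.series.mean(axis=1, keepdims=True)
        sd = x.std(axis=1)
        degenerate = sd == 0
        if degenerate.any():
            bad = [mat.parcel_names[i] for i in np.flatnonzero(degenerate)]
            warnings.warn(
                f"zero-variance series for parcel(s) {bad}; correlations set "
                f"to NaN", stacklevel=3,
            )
            sd = np.where(degenerate, np.nan, sd)
        return x / sd[:, None], degenerate

    zw, _ = zscore(wm_ts)
    zg, _ = zscore(gm_ts)
    cc = np.clip(zw @ zg.T / wm_ts.n_timepoints, -1.0, 1.0)
    return WmGmConnectome(cc, list(wm_ts.parcel_labels), list(gm_ts.parcel_labels))


def mcc(connectome: WmGmConnectome, use_abs: bool = False) -> BundleMcc:
    """Bundle- and region-level mean correlation coefficients.

    The bundle value is the signed arithmetic mean of the finite CCs in its
    row (``use_abs=True`` averages magnitudes instead); the region value is
    the column mean likewise.  A bundle row with no finite entry raises.
    """
    cc = np.abs(connectome.cc) if use_abs else connectome.cc
    finite = np.isfinite(cc)
    if (~finite.any(axis=1)).any():
        bad = [connectome.bundle_labels[i]
               for i in np.flatnonzero(~finite.any(axis=1))]
        raise ValueError(f"bundle rows {bad} have no finite correlation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN region cols
        bundle = np.nanmean(cc, axis=1)
        region = np.nanmean(cc, axis=0)
    return BundleMcc(bundle, region,
                     list(connectome.bundle_labels),
                     list(connectome.region_labels))
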