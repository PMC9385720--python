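"""ROI mean extraction, pairwise correlations, and mCC reductions."""

import numpy as np
import pytest

from wmfc import CohortConfig, make_atlas, simulate_subject
from wmfc.connectome import (
    BundleMcc,
    RoiTimeSeriesMatrix,
    WmGmConnectome,
    extract_roi_means,
    mcc,
    pairwise_cc,
)
from wmfc.preprocess import BinaryMask, Volume4D


def ts_matrix(rows, labels=None):
    rows = np.atleast_2d(np.asarray(rows, float))
    labels = labels or list(range(1, rows.shape[0] + 1))
    return RoiTimeSeriesMatrix(labels, [f"p{l}" for l in labels], rows,
                               np.ones(rows.shape[0], int))


def hand_pearson(x, y):
    """Explicit covariance / (sx * sy) formula, double loop."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    return sxy / np.sqrt(sxx * syy)


class TestExtractRoiMeans:
    def test_identical_voxel_series_average_to_themselves(self):
        atlas = make_atlas((9, 9, 9), 1, 1, seed=0)
        data = np.zeros((9, 9, 9, 10))
        s = np.sin(np.arange(10.0))
        data[atlas.wm_parcels[0].index] = s
        wm_ts, _ = extract_roi_means(Volume4D(data), atlas)
        assert np.allclose(wm_ts.series[0], s, atol=1e-12)

    def test_opposite_series_cancel(self):
        atlas = make_atlas((9, 9, 9), 1, 1, seed=0)
        data = np.zeros((9, 9, 9, 8))
        parcel = atlas.gm_parcels[0]
        s = np.cos(np.arange(8.0))
        half = parcel.n_voxels // 2
        data[tuple(parcel.voxels[:half].T)] = s
        data[tuple(parcel.voxels[half:].T)] = -s
        _, gm_ts = extract_roi_means(Volume4D(data), atlas)
        assert np.allclose(gm_ts.series[0], 0.0, atol=1e-12)

    def test_matches_brute_force_voxel_mean(self, rng):
        atlas = make_atlas((9, 9, 9), 2, 2, seed=3)
        data = rng.standard_normal((9, 9, 9, 20))
        wm_ts, gm_ts = extract_roi_means(Volume4D(data), atlas)
        for parcel, row in zip(atlas.wm_parcels, wm_ts.series):
            expected = np.mean(
                [data[tuple(v)] for v in parcel.voxels], axis=0)
            assert np.max(np.abs(row - expected)) < 1e-12
        assert (wm_ts.n_voxels_used == [p.n_voxels for p in atlas.wm_parcels]).all()

    def test_wm_mask_restricts_bundle_voxels(self, rng):
        atlas = make_atlas((9, 9, 9), 1, 1, seed=0)
        data = rng.standard_normal((9, 9, 9, 10))
        mask = BinaryMask(atlas.wm_probability_map >= 0.95, 0.95)
        wm_ts, _ = extract_roi_means(Volume4D(data), atlas, mask)
        parcel = atlas.wm_parcels[0]
        keep = mask.mask[parcel.index]
        expected = np.mean([data[tuple(v)] for v in parcel.voxels[keep]], axis=0)
        assert np.max(np.abs(wm_ts.series[0] - expected)) < 1e-12
        assert wm_ts.n_voxels_used[0] == keep.sum() == 8

    def test_empty_intersection_names_the_parcel(self, rng):
        atlas = make_atlas((9, 9, 9), 1, 1, seed=0)
        data = rng.standard_normal((9, 9, 9, 10))
        empty = BinaryMask(np.zeros((9, 9, 9), bool), 0.99)
        with pytest.raises(ValueError, match="WM01"):
            extract_roi_means(Volume4D(data), atlas, empty)

    def test_grid_mismatch_rejected(self, rng):
        atlas = make_atlas((9, 9, 9), 1, 1, seed=0)
        with pytest.raises(ValueError, match="grid"):
            extract_roi_means(Volume4D(rng.standard_normal((5, 5, 5, 10))),
                              atlas)


class TestPairwiseCc:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(30)
        conn = pairwise_cc(ts_matrix([x]), ts_matrix([x], labels=[101]))
        assert abs(conn.cc[0, 0] - 1.0) < 1e-12

    def test_antisymmetry(self, rng):
        x = rng.standard_normal(30)
        conn = pairwise_cc(ts_matrix([x]), ts_matrix([-x], labels=[101]))
        assert abs(conn.cc[0, 0] + 1.0) < 1e-12

    def test_matches_hand_coded_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        conn = pairwise_cc(ts_matrix([x]), ts_matrix([y], labels=[101]))
        assert abs(conn.cc[0, 0] - hand_pearson(x, y)) < 1e-12

    def test_oracle_on_random_matrix(self, rng):
        wm = ts_matrix(rng.standard_normal((4, 25)))
        gm = ts_matrix(rng.standard_normal((6, 25)),
                       labels=list(range(101, 107)))
        conn = pairwise_cc(wm, gm)
        for i in range(4):
            for j in range(6):
                assert abs(conn.cc[i, j]
                           - hand_pearson(wm.series[i], gm.series[j])) < 1e-10

    def test_affine_invariance_and_sign_flip(self, rng):
        x = rng.standard_normal((2, 40))
        g = rng.standard_normal((3, 40))
        base = pairwise_cc(ts_matrix(x), ts_matrix(g, labels=[101, 102, 103]))
        scaled = x.copy()
        scaled[0] = 2.5 * x[0] + 7.0
        up = pairwise_cc(ts_matrix(scaled), ts_matrix(g, labels=[101, 102, 103]))
        assert np.max(np.abs(up.cc - base.cc)) < 1e-10
        flipped = x.copy()
        flipped[0] = -1.5 * x[0] + 2.0
        down = pairwise_cc(ts_matrix(flipped),
                           ts_matrix(g, labels=[101, 102, 103]))
        assert np.max(np.abs(down.cc[0] + base.cc[0])) < 1e-10
        assert np.max(np.abs(down.cc[1] - base.cc[1])) < 1e-10

    def test_zero_variance_row_becomes_nan_with_warning(self, rng):
        wm = ts_matrix(np.vstack([np.full(20, 3.0), rng.standard_normal(20)]))
        gm = ts_matrix(rng.standard_normal((2, 20)), labels=[101, 102])
        with pytest.warns(UserWarning, match="zero-variance"):
            conn = pairwise_cc(wm, gm)
        assert np.isnan(conn.cc[0]).all()
        assert np.isfinite(conn.cc[1]).all()

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError, match="timepoint"):
            pairwise_cc(ts_matrix(rng.standard_normal((1, 10))),
                        ts_matrix(rng.standard_normal((1, 12)), labels=[101]))


class TestMcc:
    def make_connectome(self, cc):
        cc = np.atleast_2d(np.asarray(cc, float))
        return WmGmConnectome(cc, list(range(1, cc.shape[0] + 1)),
                              list(range(101, 101 + cc.shape[1])))

    def test_constant_row(self):
        res = mcc(self.make_connectome(np.full((1, 5), 0.3)))
        assert abs(res.bundle_mcc[0] - 0.3) < 1e-12

    def test_symmetric_row_averages_to_zero(self):
        res = mcc(self.make_connectome([[1.0, -1.0]]))
        assert abs(res.bundle_mcc[0]) < 1e-12

    def test_matches_brute_force_mean(self, rng):
        cc = rng.uniform(-1, 1, size=(3, 82))
        res = mcc(self.make_connectome(cc))
        for i in range(3):
            assert abs(res.bundle_mcc[i] - sum(cc[i]) / 82) < 1e-12
        for j in range(82):
            assert abs(res.region_mcc[j] - sum(cc[:, j]) / 3) < 1e-12

    def test_row_permutation_permutes_mcc(self, rng):
        cc = rng.uniform(-1, 1, size=(4, 6))
        perm = [2, 0, 3, 1]
        base = mcc(self.make_connectome(cc))
        permuted = mcc(self.make_connectome(cc[perm]))
        assert np.allclose(permuted.bundle_mcc, base.bundle_mcc[perm])

    def test_abs_option_averages_magnitudes(self):
        res = mcc(self.make_connectome([[0.5, -0.5]]), use_abs=True)
        assert abs(res.bundle_mcc[0] - 0.5) < 1e-12

    def test_nan_entries_excluded_from_mean(self):
        cc = np.array([[0.4, np.nan, 0.2]])
        res = mcc(self.make_connectome(cc))
        assert abs(res.bundle_mcc[0] - 0.3) < 1e-12

    def test_all_nan_row_rejected(self):
        with pytest.raises(ValueError, match="no finite"):
            mcc(self.make_connectome([[np.nan, np.nan]]))


class TestOnSimulatedSubject:
    def test_full_coupling_recovers_unit_entry(self):
        # noise-free subject, weight 1 to a single region: cc entry = 1
        atlas = make_atlas((9, 9, 9), 1, 2, seed=2)
        cfg = CohortConfig(noise_sd=0.0, drift_amplitude=0.0,
                           baseline_coupling=1.0,
                           coupling_weights=np.array([[1.0, 0.0]]),
                           affected_bundles=[1])
        s = simulate_subject(atlas, cfg, "control", rng=3)
        wm_ts, gm_ts = extract_roi_means(s.volume, atlas)
        conn = pairwise_cc(wm_ts, gm_ts)
        assert abs(conn.cc[0, 0] - 1.0) < 1e-8
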