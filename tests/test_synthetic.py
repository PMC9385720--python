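"""Atlas construction and the synthetic cohort generator."""

import numpy as np
import pytest

from wmfc import (
    CohortConfig,
    make_atlas,
    simulate_cohort,
    simulate_subject,
)
from wmfc.connectome import extract_roi_means, pairwise_cc
from wmfc.spectral import welch_psd
from wmfc.synthetic import ScoreModel, default_coupling


def tiny_atlas(seed=0, n_wm=1, n_gm=1):
    return make_atlas((9, 9, 9), n_wm, n_gm, seed=seed)


def noise_free_config(**kw):
    kw.setdefault("noise_sd", 0.0)
    kw.setdefault("drift_amplitude", 0.0)
    kw.setdefault("baseline_coupling", 1.0)
    kw.setdefault("coupling_weights", np.array([[1.0]]))
    kw.setdefault("affected_bundles", [1])
    return CohortConfig(**kw)


def bundle_region_cc(subject, atlas):
    wm_ts, gm_ts = extract_roi_means(subject.volume, atlas)
    return pairwise_cc(wm_ts, gm_ts).cc


class TestMakeAtlas:
    def test_constructive_example(self):
        atlas = make_atlas((24, 24, 12), 6, 10, seed=1)
        assert atlas.n_wm == 6 and atlas.n_gm == 10
        labels = atlas.wm_labels + atlas.gm_labels
        assert len(set(labels)) == 16
        for p in atlas.wm_parcels + atlas.gm_parcels:
            assert p.n_voxels >= 8
        # disjointness and bounds are enforced by AtlasSpec.validate()
        atlas.validate()

    def test_deterministic(self):
        a = make_atlas((24, 24, 12), 6, 10, seed=1)
        b = make_atlas((24, 24, 12), 6, 10, seed=1)
        assert np.array_equal(a.label_volume(), b.label_volume())
        assert np.array_equal(a.wm_probability_map, b.wm_probability_map)

    def test_grid_too_small_raises_sizing_error(self):
        with pytest.raises(ValueError, match="slots"):
            make_atlas((4, 4, 1), 48, 82)

    def test_wm_probability_interior_and_rim(self):
        atlas = make_atlas((14, 14, 9), 2, 2, seed=0)
        prob = atlas.wm_probability_map
        for p in atlas.wm_parcels:
            vals = prob[p.index]
            assert set(np.unique(vals)) == {0.5, 1.0}
            assert (vals == 1.0).sum() == 8  # 2x2x2 interior of a 4x4x4 block
        for p in atlas.gm_parcels:
            assert (prob[p.index] == 0.0).all()


class TestSimulateSubject:
    def test_noise_free_full_coupling_gives_unit_correlation(self):
        atlas = tiny_atlas()
        cfg = noise_free_config()
        s = simulate_subject(atlas, cfg, "control", rng=1)
        cc = bundle_region_cc(s, atlas)
        assert abs(cc[0, 0] - 1.0) < 1e-8

    def test_fully_decoupled_patient_correlation_near_zero(self):
        # multiplier 0: the bundle carries independent band-limited noise,
        # so |CC| stays small for 200 timepoints in nearly every seed
        atlas = tiny_atlas()
        cfg = noise_free_config(effect_multiplier=0.0, severity_jitter=0.0)
        small = sum(
            abs(bundle_region_cc(
                simulate_subject(atlas, cfg, "patient", "early", rng=seed),
                atlas)[0, 0]) < 0.3
            for seed in range(100)
        )
        assert small >= 95

    def test_bit_identical_under_same_seed(self, small_atlas):
        cfg = CohortConfig(seed=3)
        a = simulate_subject(small_atlas, cfg, "patient", "early", rng=7)
        b = simulate_subject(small_atlas, cfg, "patient", "early", rng=7)
        assert np.array_equal(a.volume.data, b.volume.data)
        assert a.clinical_scores == b.clinical_scores
        assert a.duration_years == b.duration_years

    def test_unknown_affected_bundle_rejected(self, small_atlas):
        cfg = CohortConfig(affected_bundles=[99])
        with pytest.raises(ValueError, match="absent from atlas"):
            simulate_subject(small_atlas, cfg, "patient", "early", rng=0)

    def test_effect_monotonicity(self):
        # expected planted-bundle CC is non-increasing in the deficit,
        # checked on a 3-point multiplier grid averaged over 50 seeds
        atlas = tiny_atlas()
        means = []
        for m in (1.0, 0.6, 0.2):
            cfg = noise_free_config(effect_multiplier=m, severity_jitter=0.0)
            ccs = [
                bundle_region_cc(
                    simulate_subject(atlas, cfg, "patient", "early", rng=seed),
                    atlas)[0, 0]
                for seed in range(50)
            ]
            means.append(np.mean(ccs))
        assert means[0] > means[1] > means[2]

    def test_latent_power_concentrated_in_band(self):
        # >= 90% of a noise-free latent signal's Welch power in 0.01-0.08 Hz
        atlas = tiny_atlas()
        cfg = noise_free_config()
        s = simulate_subject(atlas, cfg, "control", rng=11)
        _, gm_ts = extract_roi_means(s.volume, atlas)
        psd = welch_psd(gm_ts.series[0], tr_seconds=2.0)
        in_band = (psd.frequencies_hz >= 0.01) & (psd.frequencies_hz <= 0.08)
        assert psd.power[in_band].sum() / psd.power.sum() >= 0.90

    def test_scores_exact_affine_in_deficit_without_noise(self, small_atlas):
        model = ScoreModel(noise_sd=0.0)
        cfg = CohortConfig(score_model=model, affected_bundles=[1, 2, 3, 4, 5, 6])
        s = simulate_subject(small_atlas, cfg, "patient", "nonearly", rng=5)
        d = s.planted_deficit[:6]
        expected = {
            "UMSARS-I": 3.0 + 22.0 * d[[0, 1]].mean(),
            "UMSARS-II": 1.0 + 20.0 * d[0],
            "SARA": 2.0 + 22.0 * d.mean(),
        }
        for name, val in expected.items():
            assert abs(s.clinical_scores[name] - val) < 1e-12

    def test_control_invariants(self, small_atlas):
        s = simulate_subject(small_atlas, CohortConfig(), "control", rng=2)
        assert s.stage == "none" and s.duration_years is None
        assert (s.planted_deficit == 0).all()


class TestSimulateCohort:
    def test_counts_and_stage_split(self, small_atlas):
        cfg = CohortConfig(n_per_group=15, seed=0)
        cohort = simulate_cohort(small_atlas, cfg)
        groups = [s.group for s in cohort]
        assert groups.count("control") == 15
        stages = [s.stage for s in cohort if s.group == "patient"]
        assert stages.count("early") == 8 and stages.count("nonearly") == 7
        assert len(cohort) == 30

    def test_early_stage_matches_duration(self, small_atlas):
        cohort = simulate_cohort(small_atlas, CohortConfig(seed=4))
        for s in cohort:
            if s.group == "patient":
                assert (s.duration_years <= 2.0) == (s.stage == "early")

    def test_deterministic_under_fixed_seed(self, small_atlas):
        cfg = CohortConfig(n_per_group=3, n_controls=3, seed=9)
        a = simulate_cohort(small_atlas, cfg)
        b = simulate_cohort(small_atlas, cfg)
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            assert np.array_equal(sa.volume.data, sb.volume.data)

    def test_subject_seeds_stable_under_cohort_growth(self, small_atlas):
        # enlarging the cohort must not perturb earlier subjects
        small = simulate_cohort(small_atlas, CohortConfig(
            n_per_group=2, n_controls=2, seed=9))
        large = simulate_cohort(small_atlas, CohortConfig(
            n_per_group=2, n_controls=4, seed=9))
        assert np.array_equal(small[0].volume.data, large[0].volume.data)
        assert np.array_equal(small[1].volume.data, large[1].volume.data)

    def test_n_controls_override(self, small_atlas):
        cohort = simulate_cohort(small_atlas, CohortConfig(
            n_per_group=4, n_controls=6, seed=1))
        assert sum(s.group == "control" for s in cohort) == 6
        assert len(cohort) == 10


class TestDefaultCoupling:
    def test_shape_and_range(self):
        w = default_coupling(8, 10)
        assert w.shape == (8, 10)
        assert (w >= 0.5).all() and (w <= 1.0).all()

    def test_strongest_at_home_region(self):
        w = default_coupling(5, 10)
        assert w[0].argmax() == 0
        assert w[0].min() == w[0][5]  # far side of the ring
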