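"""Packaged replication experiments on synthetic cohorts.

Each function simulates cohorts under the generator's default study
conditions, runs them through the real analysis path (preprocess -> ROI
means -> connectome -> mCC -> inference/classification/regression), and
measures an operating characteristic of the method: false-positive
calibration of the 1/k rule, recovery of planted bundle deficits,
leave-one-out classification performance, and stepwise score-regression
recovery.  The test suite and the reproduction script both drive these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import stepwise_regression
from .classify import FeatureMatrix, loocv_classify
from .group_stats import compare_parcels
from .io import cohort_feature_table
from .synthetic import (
    AtlasSpec, CohortConfig, GROUP_CONTROL, GROUP_PATIENT, STAGE_EARLY,
    make_atlas, simulate_cohort,
)

#: reduced atlas used for replicate experiments: 8 WM bundles x 10 GM
#: regions on a 14 x 14 x 9 grid (4-voxel cube parcels), sized so hundreds
#: of cohorts run on one CPU in minutes
REDUCED_GRID = (14, 14, 9)
REDUCED_N_WM = 8
REDUCED_N_GM = 10
#: first six bundles carry the planted deficit; bundles 7-8 stay intact
AFFECTED_BUNDLES = [1, 2, 3, 4, 5, 6]


def reduced_atlas(seed: int = 1) -> AtlasSpec:
    return make_atlas(REDUCED_GRID, REDUCED_N_WM, REDUCED_N_GM, seed=seed)


def cohort_bundle_mcc(
    atlas: AtlasSpec, config: CohortConfig
) -> tuple[np.ndarray, pd.DataFrame, list[int]]:
    """Simulate one cohort and return its (subjects x bundles) mCC matrix."""
    cohort = simulate_cohort(atlas, config)
    feats = cohort_feature_table(cohort, atlas)
    return feats["bundle_mcc"], feats["meta"], feats["bundle_labels"]


def null_calibration(
    n_replicates: int = 200, seed: int = 0, atlas: AtlasSpec | None = None
) -> dict:
    """False-positive calibration of the 1/k rule on no-effect cohorts.

    Simulates ``n_replicates`` cohorts with the group effect removed
    (multiplier 1, 15 vs 15) and counts bundles flagged at alpha = 1/k.
    The correction's contract is one false positive on average.
    """
    atlas = atlas or reduced_atlas()
    counts = []
    for r in range(n_replicates):
        cfg = CohortConfig(seed=seed + r, effect_multiplier=1.0, n_controls=15)
        bm, meta, _ = cohort_bundle_mcc(atlas, cfg)
        patients = (meta["group"] == GROUP_PATIENT).to_numpy()
        comp = compare_parcels(bm[patients], bm[~patients])
        counts.append(comp.n_significant)
    counts = np.asarray(counts)
    return {
        "mean_flagged": float(counts.mean()),
        "counts": counts,
        "alpha": 1.0 / atlas.n_wm,
    }


def planted_recovery(
    n_seeds: int = 20, seed: int = 0, effect_multiplier: float = 0.5,
    atlas: AtlasSpec | None = None,
) -> dict:
    """Recovery of planted bundle deficits by the 1/k-corrected t tests.

    Each replicate plants the default deficit (multiplier 0.5) in six of
    eight bundles and checks that >= 5/6 affected bundles are flagged with
    at most one unaffected bundle flagged.
    """
    atlas = atlas or reduced_atlas()
    affected = set(AFFECTED_BUNDLES)
    detected, fp_ok, joint = [], [], []
    for r in range(n_seeds):
        cfg = CohortConfig(seed=seed + r, effect_multiplier=effect_multiplier,
                           affected_bundles=AFFECTED_BUNDLES)
        bm, meta, labels = cohort_bundle_mcc(atlas, cfg)
        patients = (meta["group"] == GROUP_PATIENT).to_numpy()
        comp = compare_parcels(bm[patients], bm[~patients],
                               parcel_labels=labels)
        flagged = set(comp.significant_labels)
        hit = len(flagged & affected) >= 5
        clean = len(flagged - affected) <= 1
        detected.append(hit)
        fp_ok.append(clean)
        joint.append(hit and clean)
    return {
        "detection_rate": float(np.mean(detected)),
        "fp_ok_rate": float(np.mean(fp_ok)),
        "joint_rate": float(np.mean(joint)),
        "n_seeds": n_seeds,
    }


def classification_performance(
    n_seeds: int = 20, seed: int = 0, effect_multiplier: float | None = 0.3,
    early_vs_control: bool = True, atlas: AtlasSpec | None = None,
) -> dict:
    """LOOCV SVM performance on affected-bundle mCC features.

    ``effect_multiplier=0.3`` gives strong-effect cohorts (early-stage
    patients vs controls); ``effect_multiplier=1.0`` gives null cohorts
    where the AUC should hover around chance.
    """
    atlas = atlas or reduced_atlas()
    cols = [lbl - 1 for lbl in AFFECTED_BUNDLES]
    aucs, sens, spec = [], [], []
    for r in range(n_seeds):
        cfg = CohortConfig(seed=seed + r, effect_multiplier=effect_multiplier,
                           affected_bundles=AFFECTED_BUNDLES)
        bm, meta, _ = cohort_bundle_mcc(atlas, cfg)
        if early_vs_control:
            sel = ((meta["stage"] == STAGE_EARLY)
                   | (meta["group"] == GROUP_CONTROL)).to_numpy()
        else:
            sel = np.ones(len(meta), dtype=bool)
        y = (meta.loc[sel, "group"] == GROUP_PATIENT).to_numpy().astype(int)
        res = loocv_classify(FeatureMatrix(bm[sel][:, cols], y))
        aucs.append(res.auc)
        sens.append(res.sensitivity)
        spec.append(res.specificity)
    return {
        "aucs": np.asarray(aucs),
        "mean_auc": float(np.mean(aucs)),
        "mean_sensitivity": float(np.mean(sens)),
        "mean_specificity": float(np.mean(spec)),
        "n_seeds": n_seeds,
    }


def regression_recovery(
    n_seeds: int = 50, seed: int = 0, atlas: AtlasSpec | None = None
) -> dict:
    """Stepwise recovery of the score-driving bundle.

    Under the default score model, UMSARS-II is coupled to the deficit of
    the first affected bundle.  For each replicate, the patients' UMSARS-II
    scores are regressed stepwise on the six affected bundles' mCC; success
    means the driving bundle is among the selected predictors.
    """
    atlas = atlas or reduced_atlas()
    cols = [lbl - 1 for lbl in AFFECTED_BUNDLES]
    names = [f"bundle_{lbl}" for lbl in AFFECTED_BUNDLES]
    hits, r2 = [], []
    for r in range(n_seeds):
        cfg = CohortConfig(seed=seed + r, affected_bundles=AFFECTED_BUNDLES)
        bm, meta, _ = cohort_bundle_mcc(atlas, cfg)
        patients = (meta["group"] == GROUP_PATIENT).to_numpy()
        res = stepwise_regression(
            meta.loc[patients, "UMSARS-II"].to_numpy(),
            bm[patients][:, cols], feature_names=names,
        )
        hits.append("bundle_1" in res.selected_predictors)
        r2.append(res.r_squared)
    return {
        "recovery_rate": float(np.mean(hits)),
        "mean_r_squared": float(np.mean(r2)),
        "n_seeds": n_seeds,
    }
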