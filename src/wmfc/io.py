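"""File formats, configuration, and end-to-end pipeline orchestration.

Volumes travel as NIfTI-1 (4D signals, 3D atlas labels and WM probability),
label lookups and tabular results as TSV, configuration as YAML/JSON, and
the run report as JSON.  All inputs are assumed co-registered (post
normalization); the NIfTI affine is respected for voxel size only.

``run_pipeline`` executes simulate (optional) -> preprocess -> connectome ->
spectral -> group statistics -> classification -> score regression, persists
every intermediate table under the output directory, and stamps each output
with the hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .behavior import RegressionResult, stepwise_regression
from .classify import ClassifierConfig, FeatureMatrix, loocv_classify
from .connectome import extract_roi_means, mcc, pairwise_cc
from .group_stats import GroupComparison, compare_parcels
from .preprocess import (
    BinaryMask, Volume4D, bandpass, detrend_linear, smooth_gaussian,
    threshold_wm_mask,
)
from .spectral import band_ratios, welch_psd
from .synthetic import (
    AtlasSpec, CohortConfig, Parcel, SubjectRecord,
    GROUP_CONTROL, GROUP_PATIENT, SCORE_NAMES, STAGE_EARLY, STAGE_NONE,
    STAGE_NONEARLY,
)

logger = logging.getLogger("wmfc")

# JHU ICBM-DTI-81 white-matter bundle abbreviations: 6 commissural/midline
# structures plus 21 bilateral bundles.
_JHU_MIDLINE = ["MCP", "PCT", "GCC", "BCC", "SCC", "FX"]
_JHU_BILATERAL = [
    "CST", "ML", "ICP", "SCP", "CP", "ALIC", "PLIC", "RLIC", "ACR", "SCR",
    "PCR", "PTR", "SS", "EC", "CGC", "CGH", "FX_ST", "SLF", "SFO", "UNC",
    "TAP",
]
# 41 Brodmann areas taken bilaterally (82 GM regions).
_BRODMANN_AREAS = [
    1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 17, 18, 19, 20, 21, 22, 23, 24, 25,
    27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39, 40, 41, 42, 43, 44,
    45, 46, 47,
]


def full_label_table() -> pd.DataFrame:
    """Lookup table for the full 48-bundle / 82-region parcellation.

    Columns: label_code, name, tissue.  WM codes 1-48 (JHU bundle
    abbreviations), GM codes 101-182 (bilateral Brodmann areas).
    """
    rows = []
    code = 1
    for name in _JHU_MIDLINE:
        rows.append((code, name, "wm"))
        code += 1
    for name in _JHU_BILATERAL:
        for hemi in ("L", "R"):
            rows.append((code, f"{name}_{hemi}", "wm"))
            code += 1
    code = synthetic.GM_LABEL_OFFSET + 1
    for area in _BRODMANN_AREAS:
        for hemi in ("L", "R"):
            rows.append((code, f"BA{area}_{hemi}", "gm"))
            code += 1
    return pd.DataFrame(rows, columns=["label_code", "name", "tissue"])


# ---------------------------------------------------------------------------
# NIfTI / TSV round trips
# ---------------------------------------------------------------------------

def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def write_volume(path: str | Path, v: Volume4D) -> Path:
    """Write a 4D volume as NIfTI-1 with TR recorded in the header."""
    img = nib.Nifti1Image(v.data, _affine(v.voxel_size_mm))
    img.header.set_zooms((v.voxel_size_mm,) * 3 + (v.tr_seconds,))
    img.header.set_xyzt_units("mm", "sec")
    path = Path(path)
    nib.save(img, path)
    return path


def read_volume(path: str | Path) -> Volume4D:
    """Read a 4D NIfTI-1 volume; geometry propagates to the domain type."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4D volume, got {data.ndim}D"
        )
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return Volume4D(data, tr_seconds=tr, voxel_size_mm=float(zooms[0]))


def write_atlas(
    atlas_path: str | Path,
    labels_path: str | Path,
    atlas: AtlasSpec,
    wm_prob_path: str | Path | None = None,
) -> None:
    """Write atlas labels (3D NIfTI), lookup TSV, and WM probability map."""
    aff = _affine(atlas.voxel_size_mm)
    nib.save(nib.Nifti1Image(atlas.label_volume().astype(np.int32), aff),
             Path(atlas_path))
    rows = [(p.label, p.name, "wm") for p in atlas.wm_parcels]
    rows += [(p.label, p.name, "gm") for p in atlas.gm_parcels]
    pd.DataFrame(rows, columns=["label_code", "name", "tissue"]).to_csv(
        labels_path, sep="\t", index=False
    )
    if wm_prob_path is not None:
        nib.save(nib.Nifti1Image(atlas.wm_probability_map, aff),
                 Path(wm_prob_path))


def read_atlas(
    atlas_path: str | Path,
    labels_path: str | Path,
    wm_prob_path: str | Path | None = None,
) -> AtlasSpec:
    """Read a label volume plus lookup TSV into an AtlasSpec.

    Every nonzero code present in the volume must appear in the lookup
    table; unknown codes raise.  Without a probability map, WM voxels get
    probability 1.
    """
    img = nib.load(str(atlas_path))
    labels = np.asarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"{atlas_path}: expected a 3D label volume")
    voxel_size = float(img.header.get_zooms()[0])
    table = pd.read_csv(labels_path, sep="\t")
    required = {"label_code", "name", "tissue"}
    if not required <= set(table.columns):
        raise ValueError(f"{labels_path}: columns {sorted(required)} required")
    known = set(table["label_code"].astype(int))
    present = set(np.unique(labels).astype(int)) - {0}
    unknown = present - known
    if unknown:
        raise ValueError(
            f"{atlas_path}: label code(s) {sorted(unknown)} missing from "
            f"lookup table {labels_path}"
        )
    if wm_prob_path is not None:
        prob = np.asarray(nib.load(str(wm_prob_path)).dataobj, dtype=float)
        if prob.shape != labels.shape:
            raise ValueError("WM probability map grid differs from atlas grid")
    else:
        prob = np.zeros(labels.shape)

    wm_parcels, gm_parcels = [], []
    for _, row in table.sort_index().iterrows():
        code = int(row["label_code"])
        if code not in present:
            continue
        voxels = np.argwhere(labels == code)
        parcel = Parcel(code, str(row["name"]), voxels)
        if row["tissue"] == "wm":
            if wm_prob_path is None:
                prob[parcel.index] = 1.0
            wm_parcels.append(parcel)
        else:
            gm_parcels.append(parcel)
    return AtlasSpec(labels.shape, voxel_size, wm_parcels, gm_parcels, prob)


def write_cohort(out_dir: str | Path, cohort: list[SubjectRecord],
                 atlas: AtlasSpec) -> Path:
    """Persist a cohort: volumes, atlas, WM map, labels, manifest + scores."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_atlas(out_dir / "atlas.nii.gz", out_dir / "labels.tsv", atlas,
                out_dir / "wm_probability.nii.gz")
    rows = []
    for s in cohort:
        vol_path = out_dir / f"{s.subject_id}.nii.gz"
        write_volume(vol_path, s.volume)
        rows.append({
            "subject_id": s.subject_id,
            "group": s.group,
            "stage": s.stage,
            "duration_years": "" if s.duration_years is None
            else round(s.duration_years, 4),
            **{name: round(s.clinical_scores[name], 4) for name in SCORE_NAMES},
            "volume": vol_path.name,
        })
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    """Load a cohort written by :func:`write_cohort` (ground truth absent)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    cohort = []
    for _, row in table.iterrows():
        duration = row.get("duration_years")
        duration = None if pd.isna(duration) else float(duration)
        cohort.append(SubjectRecord(
            subject_id=str(row["subject_id"]),
            group=str(row["group"]),
            stage=str(row["stage"]),
            duration_years=duration,
            volume=read_volume(manifest_path.parent / row["volume"]),
            clinical_scores={n: float(row[n]) for n in SCORE_NAMES},
            planted_deficit=np.array([]),
        ))
    return cohort


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Either ``simulate`` parameters are given (synthetic cohort generated at
    run time) or ``manifest``/``atlas_path``/``labels_path`` point at
    existing data.
    """

    output_dir: str = "wmfc_out"
    seed: int = 0
    # synthetic branch
    simulate: bool = True
    grid_dims: tuple[int, int, int] = (24, 24, 12)
    n_wm: int = 6
    n_gm: int = 10
    # study-style arms: 15 early + 15 non-early patients, 19 controls
    cohort: CohortConfig = field(default_factory=lambda: CohortConfig(
        n_per_group=30, n_controls=19, effect_multiplier=0.5))
    write_volumes: bool = False
    # real-data branch
    manifest: str | None = None
    atlas_path: str | None = None
    labels_path: str | None = None
    wm_prob_path: str | None = None
    # preprocessing
    fwhm_mm: float = 0.0
    low_hz: float = 0.01
    high_hz: float = 0.1
    wm_threshold: float = 0.95
    # spectral
    psd_window_seconds: float = 200.0
    psd_overlap: float = 0.5
    psd_band: tuple[float, float] = (0.01, 0.08)
    # inference / classification
    alpha_wm: float | None = None  # default 1/n_wm
    alpha_gm: float | None = None  # default 1/n_gm
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    p_enter: float = 0.05
    p_remove: float = 0.10

    def validate(self) -> None:
        if not self.simulate:
            for name in ("manifest", "atlas_path", "labels_path"):
                value = getattr(self, name)
                if value is None:
                    raise ValueError(
                        f"configuration error: {name} required when "
                        f"simulate is false"
                    )
                if not Path(value).exists():
                    raise ValueError(
                        f"configuration error: {name} path {value!r} does "
                        f"not exist"
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["coupling_weights"] = (
            None if self.cohort.coupling_weights is None
            else np.asarray(self.cohort.coupling_weights).tolist()
        )
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if c.get("coupling_weights") is not None:
                c["coupling_weights"] = np.asarray(c["coupling_weights"])
            if isinstance(c.get("score_model"), dict):
                sm_d = dict(c["score_model"])
                for key in ("intercepts", "coefficients"):
                    if key in sm_d:
                        sm_d[key] = tuple(sm_d[key])
                if "targets" in sm_d:
                    sm_d["targets"] = tuple(
                        None if t is None else tuple(t) for t in sm_d["targets"]
                    )
                c["score_model"] = synthetic.ScoreModel(**sm_d)
            if isinstance(c.get("stage_profile"), dict):
                c["stage_profile"] = {
                    s: (tuple(rng), m) for s, (rng, m) in c["stage_profile"].items()
                }
            if isinstance(c.get("latent_band_hz"), (list, tuple)):
                c["latent_band_hz"] = tuple(c["latent_band_hz"])
            d["cohort"] = CohortConfig(**c)
        if isinstance(d.get("classifier"), dict):
            d["classifier"] = ClassifierConfig(**d["classifier"])
        for key in ("grid_dims", "psd_band"):
            if key in d and isinstance(d[key], (list, tuple)):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# per-subject feature extraction (preprocess -> connectome -> spectral)
# ---------------------------------------------------------------------------

def preprocess_volume(v: Volume4D, fwhm_mm: float, low_hz: float,
                      high_hz: float) -> Volume4D:
    """Canonical stage order: smooth -> detrend -> band-pass."""
    if fwhm_mm > 0:
        v = smooth_gaussian(v, fwhm_mm)
    return bandpass(detrend_linear(v), low_hz, high_hz)


def subject_features(
    v: Volume4D,
    atlas: AtlasSpec,
    wm_mask: BinaryMask,
    fwhm_mm: float = 0.0,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    psd_window_seconds: float | None = None,
    psd_overlap: float = 0.5,
    psd_band: tuple[float, float] = (0.01, 0.08),
) -> dict:
    """Run one subject through preprocessing, connectome, and spectra.

    Returns bundle/region mCC vectors and, when ``psd_window_seconds`` is
    given, per-bundle spectral band ratios.
    """
    clean = preprocess_volume(v, fwhm_mm, low_hz, high_hz)
    wm_ts, gm_ts = extract_roi_means(clean, atlas, wm_mask)
    reductions = mcc(pairwise_cc(wm_ts, gm_ts))
    out = {
        "bundle_mcc": reductions.bundle_mcc,
        "region_mcc": reductions.region_mcc,
        "bundle_labels": reductions.bundle_labels,
        "region_labels": reductions.region_labels,
    }
    if psd_window_seconds is not None:
        ratios = []
        for row in wm_ts.series:
            psd = welch_psd(row, clean.tr_seconds, psd_window_seconds,
                            psd_overlap)
            ratios.append(band_ratios(psd, *psd_band).as_tuple())
        out["band_ratios"] = np.asarray(ratios)
    return out


def cohort_feature_table(
    cohort: list[SubjectRecord],
    atlas: AtlasSpec,
    wm_threshold: float = 0.95,
    fwhm_mm: float = 0.0,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
    psd_window_seconds: float | None = None,
    psd_overlap: float = 0.5,
    psd_band: tuple[float, float] = (0.01, 0.08),
) -> dict:
    """Per-subject bundle/region mCC (and optional band-ratio) tables."""
    wm_mask = threshold_wm_mask(atlas.wm_probability_map, wm_threshold)
    bundle_rows, region_rows, ratio_rows = [], [], []
    meta = []
    bundle_labels = region_labels = None
    for s in cohort:
        feats = subject_features(
            s.volume, atlas, wm_mask, fwhm_mm, low_hz, high_hz,
            psd_window_seconds, psd_overlap, psd_band,
        )
        bundle_rows.append(feats["bundle_mcc"])
        region_rows.append(feats["region_mcc"])
        bundle_labels = feats["bundle_labels"]
        region_labels = feats["region_labels"]
        if psd_window_seconds is not None:
            ratio_rows.append(feats["band_ratios"])
        meta.append({
            "subject_id": s.subject_id, "group": s.group, "stage": s.stage,
            **s.clinical_scores,
        })
    out = {
        "meta": pd.DataFrame(meta),
        "bundle_mcc": np.asarray(bundle_rows),
        "region_mcc": np.asarray(region_rows),
        "bundle_labels": bundle_labels,
        "region_labels": region_labels,
    }
    if psd_window_seconds is not None:
        out["band_ratios"] = np.asarray(ratio_rows)  # (subject, bundle, 3)
    return out


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    config_hash: str
    output_dir: Path
    stages: list[dict]
    group_wm: GroupComparison
    group_gm: GroupComparison
    significant_bundles: list[int]
    classification: dict[str, dict]
    regression: dict[str, dict[str, RegressionResult]]
    warnings_log: list[str]

    def to_json(self) -> dict:
        # wall-clock timings stay in the sidecar timing log so that rerunning
        # an identical configuration reproduces report.json byte for byte
        return {
            "config_hash": self.config_hash,
            "stages": [s["stage"] for s in self.stages],
            "significant_bundles": self.significant_bundles,
            "n_significant_wm": self.group_wm.n_significant,
            "n_significant_gm": self.group_gm.n_significant,
            "classification": self.classification,
            "regression": {
                group: {
                    score: {
                        "selected": r.selected_predictors,
                        "coefficients": r.coefficients,
                        "r_squared": r.r_squared,
                    }
                    for score, r in by_score.items()
                }
                for group, by_score in self.regression.items()
            },
            "warnings": self.warnings_log,
        }


def _save_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# wmfc config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and persist all artifacts.

    Stochastic stages are seeded from ``config.seed``; rerunning with an
    identical configuration reproduces identical tables.
    """
    config.validate()
    chash = config.config_hash()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []
    caught: list[str] = []

    def stage(name: str, fn):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        try:
            with warnings.catch_warnings(record=True) as wlog:
                warnings.simplefilter("always")
                result = fn()
            for w in wlog:
                caught.append(f"{name}: {w.message}")
                logger.warning("stage %s: %s", name, w.message)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stages.append({
            "stage": name,
            "seconds": round(time.perf_counter() - t0, 3),
        })
        return result

    # --- data -------------------------------------------------------------
    def get_data():
        if config.simulate:
            cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
            atlas = synthetic.make_atlas(
                config.grid_dims, config.n_wm, config.n_gm, seed=config.seed
            )
            cohort = synthetic.simulate_cohort(atlas, cohort_cfg)
            if config.write_volumes:
                write_cohort(out_dir / "cohort", cohort, atlas)
            return atlas, cohort
        atlas = read_atlas(config.atlas_path, config.labels_path,
                           config.wm_prob_path)
        return atlas, read_cohort(config.manifest)

    atlas, cohort = stage("data", get_data)

    # --- preprocess + connectome + spectra ---------------------------------
    features = stage("features", lambda: cohort_feature_table(
        cohort, atlas,
        wm_threshold=config.wm_threshold, fwhm_mm=config.fwhm_mm,
        low_hz=config.low_hz, high_hz=config.high_hz,
        psd_window_seconds=config.psd_window_seconds,
        psd_overlap=config.psd_overlap, psd_band=config.psd_band,
    ))
    meta = features["meta"]
    bundle_mcc_tbl = pd.DataFrame(
        features["bundle_mcc"],
        columns=[f"bundle_{l}" for l in features["bundle_labels"]],
    )
    _save_table(pd.concat([meta, bundle_mcc_tbl], axis=1),
                out_dir / "bundle_mcc.tsv", chash)
    region_tbl = pd.DataFrame(
        features["region_mcc"],
        columns=[f"region_{l}" for l in features["region_labels"]],
    )
    _save_table(pd.concat([meta, region_tbl], axis=1),
                out_dir / "region_mcc.tsv", chash)
    ratio_rows = []
    for i, sid in enumerate(meta["subject_id"]):
        for b, lbl in enumerate(features["bundle_labels"]):
            lo, med, hi = features["band_ratios"][i, b]
            ratio_rows.append((sid, lbl, lo, med, hi))
    _save_table(
        pd.DataFrame(ratio_rows,
                     columns=["subject_id", "bundle", "low", "medium", "high"]),
        out_dir / "band_ratios.tsv", chash,
    )

    # --- group statistics ---------------------------------------------------
    is_patient = (meta["group"] == GROUP_PATIENT).to_numpy()
    is_control = (meta["group"] == GROUP_CONTROL).to_numpy()

    def run_stats():
        gw = compare_parcels(
            features["bundle_mcc"][is_patient],
            features["bundle_mcc"][is_control],
            alpha=config.alpha_wm, parcel_labels=features["bundle_labels"],
        )
        gg = compare_parcels(
            features["region_mcc"][is_patient],
            features["region_mcc"][is_control],
            alpha=config.alpha_gm, parcel_labels=features["region_labels"],
        )
        return gw, gg

    group_wm, group_gm = stage("group_stats", run_stats)
    _save_table(group_wm.to_frame(), out_dir / "group_wm.tsv", chash)
    _save_table(group_gm.to_frame(), out_dir / "group_gm.tsv", chash)
    significant = group_wm.significant_labels

    # --- classification -----------------------------------------------------
    def run_classify():
        results: dict[str, dict] = {}
        if not significant:
            caught.append("classify: no significant bundles; models skipped")
            return results
        cols = [features["bundle_labels"].index(l) for l in significant]
        X_all = features["bundle_mcc"][:, cols]
        names = [f"bundle_{l}" for l in significant]
        stage_col = meta["stage"].to_numpy()
        models = {
            "early_vs_control": (stage_col == STAGE_EARLY, is_control),
            "nonearly_vs_control": (stage_col == STAGE_NONEARLY, is_control),
            "early_vs_nonearly": (stage_col == STAGE_EARLY,
                                  stage_col == STAGE_NONEARLY),
        }
        for model, (pos, neg) in models.items():
            sel = pos | neg
            fm = FeatureMatrix(X_all[sel], pos[sel].astype(int), names)
            res = loocv_classify(fm, config.classifier)
            results[model] = {
                "auc": res.auc,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "n": int(sel.sum()),
            }
            _save_table(
                pd.DataFrame(res.roc_points, columns=["fpr", "tpr"]),
                out_dir / f"roc_{model}.tsv", chash,
            )
        return results

    classification = stage("classify", run_classify)

    # --- score regression ---------------------------------------------------
    def run_regression():
        results: dict[str, dict[str, RegressionResult]] = {}
        if not significant:
            caught.append("regress: no significant bundles; skipped")
            return results
        cols = [features["bundle_labels"].index(l) for l in significant]
        names = [f"bundle_{l}" for l in significant]
        stage_col = meta["stage"].to_numpy()
        for subgroup in (STAGE_EARLY, STAGE_NONEARLY):
            sel = stage_col == subgroup
            if sel.sum() < len(cols) + 3:
                caught.append(
                    f"regress: subgroup {subgroup} too small; skipped"
                )
                continue
            by_score = {}
            for score in SCORE_NAMES:
                by_score[score] = stepwise_regression(
                    meta.loc[sel, score].to_numpy(),
                    features["bundle_mcc"][sel][:, cols],
                    p_enter=config.p_enter, p_remove=config.p_remove,
                    feature_names=names,
                )
            results[subgroup] = by_score
        return results

    regression = stage("behavior", run_regression)

    report = RunReport(
        config_hash=chash,
        output_dir=out_dir,
        stages=stages,
        group_wm=group_wm,
        group_gm=group_gm,
        significant_bundles=significant,
        classification=classification,
        regression=regression,
        warnings_log=caught,
    )
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report.to_json(), fh, indent=2, sort_keys=True)
    with open(out_dir / "timing.log", "w") as fh:
        for s in stages:
            fh.write(f"{s['stage']}\t{s['seconds']}\n")
    config.to_yaml(out_dir / "config.yaml")
    return report
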