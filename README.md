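# wmfc — white-matter functional connectome analysis

`wmfc` analyzes resting-state fMRI signals in brain **white matter** (WM).
Although BOLD signals in WM are weaker than in gray matter (GM), their
temporal correlations with GM regions carry information about the
functional state of fiber bundles — and degenerate in diseases such as
multiple system atrophy of cerebellar type (MSA-C), where cerebellar and
brainstem tracts lose coupling with the cortex. The package is aimed at
neuroimaging researchers who want a fully testable, end-to-end
implementation of the bundle-level connectome statistics used in this kind
of study, together with a synthetic cohort generator that makes every stage
verifiable without access to patient data.

## What it computes

For each subject, after voxelwise linear detrending, zero-phase 0.01–0.1 Hz
band-pass filtering and optional 4 mm FWHM Gaussian smoothing:

- **ROI mean time series** for WM bundles (restricted to a WM
  tissue-probability mask thresholded at 0.95) and GM regions
  (48 JHU-style bundles × 82 Brodmann-style regions at full scale);
- the **WM–GM connectome**: Pearson correlation `CC(b, r)` between every
  bundle *b* and region *r*;
- the **mean correlation coefficient** of a bundle,
  `mCC(b) = (1/N_GM) Σ_r CC(b, r)`, and its region-wise companion;
- **Welch power spectral densities** (200 s Hann windows, 50 % overlap) and
  the fractions of 0.01–0.08 Hz power in its three equal sub-bands;
- **group inference**: per-bundle two-sample t tests with the `P < 1/k`
  false-positive rule (1/48 for bundles, 1/82 for regions), which bounds
  the *expected* number of false positives by one regardless of test
  dependence;
- **classification**: leave-one-out cross-validated linear SVM on the mCC
  of abnormal bundles, with sensitivity, specificity, ROC and rank-based
  AUC;
- **clinical-score regression**: bidirectional stepwise linear regression
  of UMSARS-I, UMSARS-II and SARA scores on bundle mCC features.

The synthetic cohort generator plants a known truth — band-limited latent
GM signals, bundles coupled to graded mixtures of them, stage-dependent
coupling deficits in affected bundles, and clinical scores affine in the
planted deficits — so recovery of the truth by the analysis chain is a
testable property. See `docs/methods.md` for the generative model and all
numerical conventions.

## Worked example

```python
from wmfc.io import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(
    output_dir="wmfc_out", seed=2, grid_dims=(14, 14, 9)))
print("significant bundles:", report.significant_bundles)
print("alpha used:", round(report.group_wm.alpha_used, 4))
print("early vs control:", report.classification["early_vs_control"])
```

This simulates the default study-style cohort (15 early-stage and 15
non-early patients with a coupling multiplier of 0.5 in six bundles, 19
controls) on a reduced 6-bundle × 10-region atlas, runs the full analysis,
and prints:

```
significant bundles: [1, 2, 3, 4, 5, 6]
alpha used: 0.1667
early vs control: {'auc': 0.9964912280701754, 'sensitivity': 0.9333333333333333, 'specificity': 1.0, 'n': 34}
```

All six planted bundles are flagged at the scaled `P < 1/6` rule, and the
15 early-stage patients separate almost perfectly from the 19 controls
(AUC 0.996; 14 of 15 patients and all controls classified correctly at the
SVM's native threshold). Output tables
(`bundle_mcc.tsv`, `group_wm.tsv`, `band_ratios.tsv`, ROC curves,
`report.json`) land in `wmfc_out/`, each stamped with the hash of the
configuration that produced it; rerunning the same configuration reproduces
them byte for byte.

The same pipeline is scriptable from the shell:

```bash
wmfc run --out wmfc_out --seed 2
wmfc simulate --out cohort/ --n-wm 6 --n-gm 10 --seed 1
wmfc preprocess --in sub-01.nii.gz --out clean.nii.gz --fwhm 4
```

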