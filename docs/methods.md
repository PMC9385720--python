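# Methods

This note documents the models, conventions and design choices behind
`wmfc`: what the analysis computes, what the synthetic cohort generator
emulates (and what it deliberately does not), and the numerical decisions
that a user extending or auditing the package needs to know.

## Analysis pipeline

### Preprocessing

The package starts from spatially normalized 4D volumes; slice-timing and
motion correction belong to upstream tooling and are out of scope. Stages
run in the order **smooth → detrend → band-pass**:

- **Smoothing**: isotropic Gaussian, default FWHM 4 mm
  (σ = FWHM/2.3548 converted to voxels), reflective boundary padding.
  Reflection conserves the spatial sum of every frame, so parcel means are
  not biased near volume edges. FWHM 0 disables smoothing.
- **Detrending**: voxelwise least-squares removal of intercept and slope,
  eliminating linear scanner drift. The operation is idempotent and leaves
  each series with zero mean and zero fitted slope.
- **Band-pass**: 4th-order Butterworth, default 0.01–0.1 Hz, applied
  forward and backward (`sosfiltfilt`). Zero-phase filtering matters
  because the downstream statistic is a temporal correlation: a causal
  filter would shift pass-band components and distort lagged structure.
  The filter family is a package choice; the band edges are parameters.
  Note the analysis band-passes 0.01–0.1 Hz while the spectral summary
  examines 0.01–0.08 Hz; both ranges are kept as given, deliberately
  unreconciled.
- **WM mask**: the tissue-probability map thresholded at ≥ 0.95
  (inclusive). The tight cut avoids partial-volume contamination from
  adjacent GM at the cost of shrinking bundles; a bundle that loses *all*
  voxels to the mask is a hard error rather than a silent NaN.

### Connectome and mCC

Bundle rows average only voxels in (parcel ∩ WM mask); region rows average
all parcel voxels. The connectome entry is the Pearson correlation of the
two mean series. Reductions use the **signed** mean — negative
correlations are informative and are not folded or z-transformed; an
absolute-value variant is available via `mcc(..., use_abs=True)`.
Zero-variance series produce NaN entries (with a warning) and are excluded
from mCC averaging; injecting zeros would bias bundle means toward null.
Matrix layout follows the atlas lookup-table order.

### Spectral summary

Welch estimation with 200 s Hann-tapered segments and 50 % overlap
(three segments for a 400 s acquisition at TR 2 s); segments are
mean-removed only, since linear detrending already ran voxelwise. The
0.01–0.08 Hz range is divided into three equal sub-bands; a frequency bin
belongs to the sub-band containing its center, with the last band closed
on the right. At the default TR the bin width is 0.005 Hz and each
sub-band holds exactly five bins. Only the three power *ratios* feed group
analysis, so the PSD normalization convention cancels.

### Group inference: the 1/k rule

Per-parcel two-sample t tests (Student's pooled-variance by default,
Welch's selectable) compare patients and controls on mCC. A parcel is
significant when its two-tailed p falls below `1/k`, with k the number of
parcels tested — 1/48 for bundles, 1/82 for regions, scaled to `1/n` for
reduced atlases. This is a plain per-test threshold, not a step-down
procedure: by linearity of expectation it allows one false positive on
average regardless of the number of tests or their dependence. Signed t
values are retained so coupling increases and decreases remain
distinguishable.

### Classification

A linear SVM (unit penalty) on the mCC of the significant ("abnormal")
bundles, evaluated by leave-one-out cross-validation: for each subject the
model is trained on the other n−1, with feature z-scoring fit on the
training fold only. Feature selection is fixed upstream by the group
comparison and is *not* re-selected inside folds; with seven-ish features
and n ≈ 30 this mirrors the study design it implements, at the cost of
some selection optimism. Sensitivity and specificity are read at the
classifier's native decision threshold (patients positive); the ROC and
its area come from the pooled held-out decision scores, with AUC computed
by the rank (Mann–Whitney) formulation so ties are exact.

### Clinical-score regression

Bidirectional stepwise ordinary least squares per score and patient
subgroup: forward entry of the lowest-p candidate below `p_enter = 0.05`,
backward removal above `p_remove = 0.10`, iterated to a fixed point with
ties broken by candidate order. Partial p values are coefficient t tests
in the augmented fit (equivalent to the single-variable nested-model F
test). Candidates collinear with the current model are skipped with a
warning. Entry strictly decreases the residual sum of squares, so the
procedure terminates; a step-count bound of twice the candidate count is
asserted anyway. Note that a retained predictor is only guaranteed
`p ≤ p_remove`, not `p < p_enter`.

## Synthetic cohort generator

The generator emulates the *data-generating assumptions* of a two-arm
resting-state WM-fMRI study — TR 2 s, 200 timepoints, latent activity in
0.01–0.08 Hz — with a planted ground truth:

1. Each GM region carries a latent signal: white Gaussian noise band-pass
   filtered to 0.01–0.08 Hz and variance-normalized.
2. Each WM bundle mixes the latent signals with dense, distance-graded
   weights `W[b, p] = 0.5 + 0.5·(1 − d)` (d = normalized ring distance
   between bundle and region), then standardizes the mixture. Real
   connectomes show graded correlations of every bundle with every
   region, and neighbouring tracts have similar but not identical
   profiles; the graded overlap reproduces both features.
3. A healthy bundle is only partially GM-coupled: its signal is
   `s_b = m·√c·ĝ_b + √(1 − c·m²)·η_b`, where ĝ is the standardized
   mixture, η independent band-limited noise, `c = 0.35` the baseline
   coupling fraction and `m = 1 − δ_b` the coupling multiplier. With
   `c = 0.35` the control-arm bundle mCC sits near 0.15, in the magnitude
   range reported for WM–GM correlations, and bundle-wise test statistics
   are correlated but not degenerate. Setting `c = 1`, zero noise and a
   single unit coupling weight makes the bundle reproduce its region's
   signal exactly — the identity used in tests.
4. **Disease**: affected bundles of patients receive a deficit
   `δ_{i,b} = clip(δ_stage · u_{i,b}, 0, 1)` with `u ~ Uniform(0, 2)`
   drawn per subject *and* bundle. The stage-level deficit defaults to
   0.4 for early disease (duration ≤ 2 years, drawn 0.5–2 y) and 0.6 for
   non-early (3–8 y), encoding progressive impairment; a global
   `effect_multiplier` override creates uniform-effect or null
   (`= 1.0`) cohorts. The per-subject severity jitter matters: with a
   constant per-stage deficit, clinical scores could not correlate with
   bundle measures within a group, and score regression would be
   untestable by construction.
5. **Voxels**: every voxel of a parcel receives its parcel signal plus
   independent white noise (SD 1.0, the same scale as the parcel signal)
   and a linear drift with per-voxel slope drawn within ±1 signal-SD per
   scan. Unlabeled background voxels receive pure noise, so a masking bug
   dilutes correlations instead of passing silently.
6. **Scores**: UMSARS-I, UMSARS-II and SARA are affine in planted
   deficits plus Gaussian rating noise (SD 1.5). UMSARS-I tracks the mean
   deficit of the first two affected bundles, UMSARS-II the first bundle
   alone, SARA the mean over all affected bundles. Intercepts and
   coefficients (3 + 22x, 1 + 20x, 2 + 22x) are chosen so the synthetic
   patient score distributions match the means and spreads reported for
   MSA-C cohorts (13.7 ± 7.5, 10.9 ± 6.0, 13.1 ± 7.7).

Subjects draw from per-subject generators seeded by
`(cohort seed, subject index)`, so cohorts are bit-reproducible and adding
or removing subjects does not perturb the others.

### Synthetic atlases

`make_atlas` packs disjoint 4×4×4-voxel cuboid parcels onto a gapped
lattice (≥ 8 voxels per parcel guaranteed) and assigns WM codes 1..n and
GM codes 101..100+m. The WM probability map is 1.0 in each parcel's
2×2×2-voxel interior and 0.5 on its one-voxel rim, so the default 0.95
mask strips the rim exactly as it strips partial-volume voxels in real
data. A bundled lookup table provides the full 48-bundle (JHU-style
abbreviations) × 82-region (bilateral Brodmann areas) naming for
full-scale runs.

### What the generator does not emulate

Head motion, slice-timing offsets, cardiac/respiratory physiology,
MNI-space geometry, spatial autocorrelation of noise, and any
structural/diffusion contrast. Passing tests therefore demonstrate that
the *analysis chain* recovers planted effects under idealized noise — not
that it is robust to the artifact structure of real acquisitions.
Of the structural branch of such studies, only the significant-voxel
count-to-percentage reporting utility is implemented; tensor and
fixel-based computation belong to established external toolchains.

## Replicate experiments and problem sizes

`wmfc.experiments` packages the Monte-Carlo studies used by the test suite
and the reproduction script. They run on a reduced atlas — 8 bundles × 10
regions, 14×14×9 grid, six affected bundles — with 15 subjects per arm,
sizes at which several hundred full-pipeline cohorts complete in minutes
on one CPU:

- **Null calibration** (200 replicates, multiplier 1): mean flagged
  bundles ≈ 1 at α = 1/8, the correction's contract.
- **Planted recovery** (20 replicates, multiplier 0.5): ≥ 5/6 affected
  bundles flagged with ≤ 1 false positive.
- **Classification** (20 strong-effect replicates at multiplier 0.3;
  50 null replicates): early-vs-control LOOCV AUC ≥ 0.9 under strong
  effects; chance-level AUC without effects.
- **Regression recovery** (50 replicates): stepwise selection finds the
  bundle whose deficit drives UMSARS-II.

These experiment runs skip spatial smoothing (FWHM 0): reduced-atlas
parcels are adjacent only for packing reasons, and a 4 mm kernel would
leak signal between parcels that anatomy would keep apart. The full
pipeline default keeps FWHM 4 mm.

## Numerical conventions and edge cases

- Correlations are clipped to [−1, 1] against rounding excursions.
- The WM-mask threshold is inclusive (≥ 0.95).
- Welch `n_segments = floor((N − L)/hop) + 1`, exact for all N ≥ L.
- Percentages in count summaries round half away from zero.
- Degenerate inputs fail loudly: constant regression response,
  zero-variance t-test samples, bundles with no masked voxels, one-class
  classification folds, PSD grids not covering the ratio band.
- `run_pipeline` stamps every output table with a 16-hex-digit SHA-256
  prefix of the canonical configuration JSON; wall-clock timings go to a
  sidecar log so reports stay byte-reproducible.

## Known limitations

- The 1/k correction controls the *expected* false-positive count, not a
  family-wise error rate; occasional replicates flag several null bundles
  at once, especially when bundle statistics are correlated.
- Fixing feature selection before LOOCV (as the implemented design does)
  is optimistic relative to nested selection; the package reports the
  protocol it runs and leaves nested selection to the caller.
- Stepwise regression inherits the usual selection-inference caveats:
  reported R² of selected models is biased upward under the null.
- The stage split (early ⇔ duration ≤ 2 years) is encoded as a hard
  invariant of subject records; cohorts with other conventions need their
  own stage labels.
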