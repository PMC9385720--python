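"""Synthetic resting-state cohort generator with planted WM-GM coupling.

Emulates the data-generating assumptions of a two-arm resting-state fMRI
study of white-matter functional connectivity: each gray-matter (GM) region
carries a band-limited (0.01-0.08 Hz) latent BOLD signal; each white-matter
(WM) bundle carries a unit-variance mixture of the latent signals of the GM
regions it is coupled to; every voxel of a parcel receives its parcel signal
plus independent white noise and a linear scanner drift; unlabeled
background voxels receive pure noise (so masking bugs surface as correlation
dilution rather than silent passes).

A healthy bundle carries only a fraction ``c`` (``baseline_coupling``) of
its signal variance as GM-coupled signal -- real WM BOLD correlates with
GM modestly, not perfectly -- and disease is planted as a further reduction
of that coupling.  For a bundle with coupling multiplier ``m = 1 - delta``
(``delta`` in [0, 1] is the planted deficit, 0 for controls and unaffected
bundles):

    s_b = m * sqrt(c) * ghat_b + sqrt(1 - c * m^2) * eta_b

where ``ghat_b`` is the standardized GM mixture and ``eta_b`` independent
band-limited noise.  The bundle-GM correlation therefore scales linearly
with ``m`` (m = 1: intact coupling, m = 0: fully decoupled), and with
``c = 1`` and ``noise_sd = 0`` a fully coupled bundle reproduces its
region's signal exactly.  Deficits are heterogeneous across subjects and bundles
(multiplicative severity jitter around the stage-level deficit), and
clinical scores (UMSARS-I, UMSARS-II, SARA) are affine functions of planted
bundle deficits plus noise -- the substrate for score-regression analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .preprocess import Volume4D

GROUP_CONTROL = "control"
GROUP_PATIENT = "patient"
STAGE_NONE = "none"
STAGE_EARLY = "early"
STAGE_NONEARLY = "nonearly"

SCORE_NAMES = ("UMSARS-I", "UMSARS-II", "SARA")

#: label codes: WM bundles start at 1, GM regions at this offset + 1
GM_LABEL_OFFSET = 100


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

@dataclass
class Parcel:
    """One labelled parcel: an integer code, a name, and its voxel set."""

    label: int
    name: str
    voxels: np.ndarray  # (n_voxels, 3) integer grid indices

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.intp)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
            raise ValueError("parcel voxels must be an (n, 3) index array")
        if self.label <= 0:
            raise ValueError("parcel label codes must be positive")

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]

    @property
    def index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Fancy-index tuple selecting this parcel's voxels in a 3D/4D array."""
        return tuple(self.voxels.T)


@dataclass
class AtlasSpec:
    """A labelled parcellation: WM bundles, GM regions, WM probability map."""

    grid_dims: tuple[int, int, int]
    voxel_size_mm: float
    wm_parcels: list[Parcel]
    gm_parcels: list[Parcel]
    wm_probability_map: np.ndarray

    def __post_init__(self) -> None:
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        self.wm_probability_map = np.asarray(self.wm_probability_map, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.wm_probability_map.shape != self.grid_dims:
            raise ValueError("WM probability map shape must match grid_dims")
        if (self.wm_probability_map < 0).any() or (self.wm_probability_map > 1).any():
            raise ValueError("WM probabilities must lie in [0, 1]")
        labels = [p.label for p in self.wm_parcels + self.gm_parcels]
        if len(set(labels)) != len(labels):
            raise ValueError("parcel label codes must be unique across WM and GM")
        seen: set[tuple[int, int, int]] = set()
        dims = np.asarray(self.grid_dims)
        for p in self.wm_parcels + self.gm_parcels:
            if (p.voxels < 0).any() or (p.voxels >= dims).any():
                raise ValueError(f"parcel {p.name}: voxel index outside grid")
            vox = set(map(tuple, p.voxels))
            if seen & vox:
                raise ValueError(f"parcel {p.name}: overlaps another parcel")
            seen |= vox

    @property
    def n_wm(self) -> int:
        return len(self.wm_parcels)

    @property
    def n_gm(self) -> int:
        return len(self.gm_parcels)

    @property
    def wm_labels(self) -> list[int]:
        return [p.label for p in self.wm_parcels]

    @property
    def gm_labels(self) -> list[int]:
        return [p.label for p in self.gm_parcels]

    def label_volume(self) -> np.ndarray:
        """Integer 3D volume with each voxel set to its parcel's label code."""
        vol = np.zeros(self.grid_dims, dtype=np.int32)
        for p in self.wm_parcels + self.gm_parcels:
            vol[p.index] = p.label
        return vol


def make_atlas(
    grid_dims: tuple[int, int, int],
    n_wm: int,
    n_gm: int,
    seed: int = 0,
    block: tuple[int, int, int] = (4, 4, 4),
    gap: int = 1,
    rim_thickness: int = 1,
    rim_probability: float = 0.5,
    voxel_size_mm: float = 2.0,
) -> AtlasSpec:
    """Build a reduced synthetic atlas of disjoint cuboid parcels.

    Parcels are ``block``-shaped voxel cuboids placed on a lattice with
    ``gap`` voxels between neighbours, shuffled by ``seed`` and assigned to
    WM bundles (codes 1..n_wm) then GM regions (codes 101..100+n_gm).  The
    WM probability map is 1.0 inside WM parcels except a boundary rim of
    ``rim_thickness`` voxels set to ``rim_probability`` (so a tight 0.95
    mask strips the rim, as it strips partial-volume voxels in real data).
    """
    if n_wm < 1 or n_gm < 1:
        raise ValueError("need at least one WM and one GM parcel")
    block = tuple(int(b) for b in block)
    if int(np.prod(block)) < 8:
        raise ValueError("parcel blocks must contain at least 8 voxels")
    pitch = tuple(b + gap for b in block)
    starts = []
    for dim, b, p in zip(grid_dims, block, pitch):
        n_slots = (dim - b) // p + 1 if dim >= b else 0
        starts.append(np.arange(n_slots) * p)
    capacity = int(np.prod([len(s) for s in starts]))
    needed = n_wm + n_gm
    if capacity < needed:
        min_edge = int(np.ceil(needed ** (1 / 3))) * max(pitch)
        raise ValueError(
            f"grid {grid_dims} hosts only {capacity} parcel slots of shape "
            f"{block}; {needed} required (a cube of edge >= {min_edge} "
            f"voxels would suffice)"
        )
    slots = np.array(
        [(i, j, k) for i in starts[0] for j in starts[1] for k in starts[2]]
    )
    rng = np.random.default_rng(seed)
    chosen = slots[rng.permutation(capacity)[:needed]]

    offsets = np.array(
        [(i, j, k)
         for i in range(block[0]) for j in range(block[1]) for k in range(block[2])]
    )

    def parcel_voxels(start: np.ndarray) -> np.ndarray:
        return start[None, :] + offsets

    wm_parcels = [
        Parcel(i + 1, f"WM{i + 1:02d}", parcel_voxels(chosen[i]))
        for i in range(n_wm)
    ]
    gm_parcels = [
        Parcel(GM_LABEL_OFFSET + i + 1, f"GM{i + 1:02d}",
               parcel_voxels(chosen[n_wm + i]))
        for i in range(n_gm)
    ]

    prob = np.zeros(grid_dims, dtype=float)
    interior_lo = rim_thickness
    interior_hi = np.asarray(block) - rim_thickness
    for p in wm_parcels:
        prob[p.index] = rim_probability
        rel = p.voxels - p.voxels.min(axis=0)
        interior = np.all((rel >= interior_lo) & (rel < interior_hi), axis=1)
        if rim_thickness > 0 and not interior.any():
            raise ValueError(
                f"rim_thickness {rim_thickness} leaves no interior voxel in "
                f"block {block}"
            )
        prob[tuple(p.voxels[interior].T)] = 1.0

    return AtlasSpec(grid_dims, voxel_size_mm, wm_parcels, gm_parcels, prob)


# ---------------------------------------------------------------------------
# cohort configuration
# ---------------------------------------------------------------------------

def default_coupling(n_wm: int, n_gm: int) -> np.ndarray:
    """Default bundle-region coupling: dense, distance-graded weights.

    Each bundle couples to every GM region, most strongly to regions near
    its "home" position on a ring layout and tapering to half weight at the
    far side: ``W[b, p] = 0.5 + 0.5 * (1 - d(b, p))`` with ``d`` the
    normalized ring distance.  This mimics resting-state connectomes, where
    a bundle shows graded correlations with all cortical regions rather
    than a sparse block, and neighbouring bundles have similar but not
    identical regional profiles.
    """
    w = np.empty((n_wm, n_gm))
    for b in range(n_wm):
        center = b * n_gm / n_wm
        raw = np.abs(np.arange(n_gm) - center)
        ring = np.minimum(raw, n_gm - raw) / (n_gm / 2.0)
        w[b] = 0.5 + 0.5 * (1.0 - ring)
    return w

@dataclass
class ScoreModel:
    """Affine mapping from planted bundle deficits to clinical scores.

    Each score equals ``intercept + coefficient * mean(deficit[targets]) +
    Normal(0, noise_sd)``, where ``targets`` indexes into the affected-bundle
    list (``None`` = all affected bundles).  Defaults are chosen so that at
    the default stage deficits the synthetic score distributions match the
    patient means and spreads reported for MSA-C cohorts (UMSARS-I
    13.7 +/- 7.5, UMSARS-II 10.9 +/- 6.0, SARA 13.1 +/- 7.7): most of a
    score's variance comes from the planted deficit, with a modest
    rating-noise floor.
    """

    intercepts: tuple[float, float, float] = (3.0, 1.0, 2.0)
    coefficients: tuple[float, float, float] = (22.0, 20.0, 22.0)
    targets: tuple[tuple[int, ...] | None, ...] = ((0, 1), (0,), None)
    noise_sd: float = 1.5

    def evaluate(self, deficits_affected: np.ndarray,
                 rng: np.random.Generator) -> dict[str, float]:
        scores: dict[str, float] = {}
        for name, a, b, tgt in zip(
            SCORE_NAMES, self.intercepts, self.coefficients, self.targets
        ):
            if tgt is None:
                d = deficits_affected
            else:
                # drop target indices beyond the affected list (small atlases)
                idx = [i for i in tgt if i < deficits_affected.size]
                d = deficits_affected[idx] if idx else deficits_affected
            mean_deficit = float(d.mean()) if d.size else 0.0
            noise = rng.normal(0.0, self.noise_sd) if self.noise_sd > 0 else 0.0
            scores[name] = a + b * mean_deficit + noise
        return scores


@dataclass
class CohortConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the emulated acquisition (TR = 2 s, 200 timepoints,
    latent band 0.01-0.08 Hz) and arm sizes of the emulated study design
    (15 patients per stage, matched controls).  ``stage_profile`` maps each
    patient stage to a (duration-years range, coupling multiplier); the
    non-early stage is more severe (smaller multiplier).  Setting
    ``effect_multiplier`` overrides the multiplier of every stage (1.0
    produces a null cohort with no group effect).
    """

    n_per_group: int = 15
    n_controls: int | None = None
    tr_seconds: float = 2.0
    n_timepoints: int = 200
    coupling_weights: np.ndarray | None = None
    affected_bundles: list[int] | None = None
    effect_multiplier: float | None = None
    stage_profile: dict[str, tuple[tuple[float, float], float]] = field(
        default_factory=lambda: {
            STAGE_EARLY: ((0.5, 2.0), 0.6),
            STAGE_NONEARLY: ((3.0, 8.0), 0.4),
        }
    )
    severity_jitter: float = 1.0
    baseline_coupling: float = 0.35
    drift_amplitude: float = 1.0
    noise_sd: float = 1.0
    latent_band_hz: tuple[float, float] = (0.01, 0.08)
    score_model: ScoreModel = field(default_factory=ScoreModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        nyq = 0.5 / self.tr_seconds
        lo, hi = self.latent_band_hz
        if not (0.0 < lo < hi < nyq):
            raise ValueError(
                f"latent band {self.latent_band_hz} must lie inside (0, {nyq:g})"
            )
        for m in self.stage_multipliers().values():
            if not (0.0 <= m <= 1.0):
                raise ValueError("effect multipliers must lie in [0, 1]")
        if self.severity_jitter < 0:
            raise ValueError("severity_jitter must be non-negative")
        if not (0.0 < self.baseline_coupling <= 1.0):
            raise ValueError("baseline_coupling must lie in (0, 1]")
        if self.noise_sd < 0 or self.drift_amplitude < 0:
            raise ValueError("noise_sd and drift_amplitude must be non-negative")

    def stage_multipliers(self) -> dict[str, float]:
        """Per-stage coupling multipliers after any global override."""
        if self.effect_multiplier is not None:
            return {s: self.effect_multiplier for s in self.stage_profile}
        return {s: m for s, ((_, _), m) in self.stage_profile.items()}

    def resolve_affected(self, atlas: AtlasSpec) -> list[int]:
        """Affected bundle labels, validated against the atlas."""
        if self.affected_bundles is None:
            return atlas.wm_labels[: min(6, atlas.n_wm)]
        missing = set(self.affected_bundles) - set(atlas.wm_labels)
        if missing:
            raise ValueError(
                f"affected bundle labels {sorted(missing)} absent from atlas"
            )
        return list(self.affected_bundles)

    def resolve_weights(self, atlas: AtlasSpec) -> np.ndarray:
        """Coupling-weight matrix (n_wm x n_gm), default overlapping windows."""
        if self.coupling_weights is None:
            return default_coupling(atlas.n_wm, atlas.n_gm)
        w = np.asarray(self.coupling_weights, dtype=float)
        if w.shape != (atlas.n_wm, atlas.n_gm):
            raise ValueError(
                f"coupling_weights shape {w.shape} != ({atlas.n_wm}, {atlas.n_gm})"
            )
        if (w < 0).any() or (w > 1).any():
            raise ValueError("coupling weights must lie in [0, 1]")
        return w


@dataclass
class SubjectRecord:
    """One simulated subject: volume, group/stage metadata, scores, truth."""

    subject_id: str
    group: str
    stage: str
    duration_years: float | None
    volume: Volume4D
    clinical_scores: dict[str, float]
    planted_deficit: np.ndarray  # per WM bundle, atlas order

    def __post_init__(self) -> None:
        if self.group not in (GROUP_CONTROL, GROUP_PATIENT):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == GROUP_CONTROL:
            if self.stage != STAGE_NONE or self.duration_years is not None:
                raise ValueError("controls must have stage 'none' and no duration")
        else:
            if self.stage not in (STAGE_EARLY, STAGE_NONEARLY):
                raise ValueError(f"unknown patient stage {self.stage!r}")
            if self.duration_years is None:
                raise ValueError("patients require a disease duration")
            early = self.duration_years <= 2.0
            if early != (self.stage == STAGE_EARLY):
                raise ValueError(
                    "stage/duration mismatch: early <=> duration <= 2 years"
                )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _band_limited_noise(
    n_series: int, n_timepoints: int, tr_seconds: float,
    band_hz: tuple[float, float], rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-pass filtered to ``band_hz``."""
    x = rng.standard_normal((n_series, n_timepoints))
    sos = signal.butter(4, band_hz, btype="bandpass", fs=1.0 / tr_seconds,
                        output="sos")
    x = signal.sosfiltfilt(sos, x, axis=-1)
    return _standardize_rows(x)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("cannot standardize a zero-variance series")
    return x / sd


def simulate_subject(
    atlas: AtlasSpec,
    config: CohortConfig,
    group: str,
    stage: str = STAGE_NONE,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "sub-01",
    duration_years: float | None = None,
) -> SubjectRecord:
    """Simulate one subject's 4D volume, clinical scores, and ground truth.

    Draw order is fixed (GM latents, bundle noise, severities, duration,
    voxel noise, drift, score noise) so a given ``rng`` state reproduces the
    subject bit-for-bit.
    """
    if group not in (GROUP_CONTROL, GROUP_PATIENT):
        raise ValueError(f"unknown group {group!r}")
    if group == GROUP_CONTROL:
        stage = STAGE_NONE
    elif stage not in (STAGE_EARLY, STAGE_NONEARLY):
        raise ValueError("patients require stage 'early' or 'nonearly'")
    rng = np.random.default_rng(rng)

    T = config.n_timepoints
    W = config.resolve_weights(atlas)
    affected = config.resolve_affected(atlas)
    wm_labels = atlas.wm_labels
    affected_pos = [wm_labels.index(lbl) for lbl in affected]

    # latent GM signals and standardized per-bundle mixtures
    latents = _band_limited_noise(
        atlas.n_gm, T, config.tr_seconds, config.latent_band_hz, rng
    )
    mixtures = _standardize_rows(W @ latents)
    eta = _band_limited_noise(
        atlas.n_wm, T, config.tr_seconds, config.latent_band_hz, rng
    )

    # planted deficits: stage-level deficit with per-(subject, bundle) jitter
    deficits = np.zeros(atlas.n_wm)
    if group == GROUP_PATIENT:
        base = 1.0 - config.stage_multipliers()[stage]
        j = config.severity_jitter
        u = rng.uniform(1.0 - j, 1.0 + j, size=len(affected_pos))
        deficits[affected_pos] = np.clip(base * u, 0.0, 1.0)
        if duration_years is None:
            lo, hi = config.stage_profile[stage][0]
            duration_years = float(rng.uniform(lo, hi))
    else:
        duration_years = None

    m = (1.0 - deficits)[:, None]
    c = config.baseline_coupling
    bundle_signals = (m * np.sqrt(c)) * mixtures + np.sqrt(1.0 - c * m ** 2) * eta

    # assemble the volume: noise + drift everywhere, parcel signals on top
    shape = atlas.grid_dims + (T,)
    if config.noise_sd > 0:
        data = rng.standard_normal(shape) * config.noise_sd
    else:
        data = np.zeros(shape)
    if config.drift_amplitude > 0:
        slope = rng.uniform(-config.drift_amplitude, config.drift_amplitude,
                            size=atlas.grid_dims)
        data += slope[..., None] * np.linspace(0.0, 1.0, T)
    for b, parcel in enumerate(atlas.wm_parcels):
        data[parcel.index] += bundle_signals[b]
    for g, parcel in enumerate(atlas.gm_parcels):
        data[parcel.index] += latents[g]

    scores = config.score_model.evaluate(deficits[affected_pos], rng)

    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        stage=stage,
        duration_years=duration_years,
        volume=Volume4D(data, config.tr_seconds, atlas.voxel_size_mm),
        clinical_scores=scores,
        planted_deficit=deficits,
    )


def subject_seed(config_seed: int, subject_index: int) -> np.random.SeedSequence:
    """Deterministic per-subject seed; independent of cohort composition."""
    return np.random.SeedSequence(entropy=config_seed,
                                  spawn_key=(subject_index,))


def simulate_cohort(atlas: AtlasSpec, config: CohortConfig) -> list[SubjectRecord]:
    """Simulate a full two-arm cohort.

    Controls come first, then early-stage patients (``ceil(n_per_group/2)``)
    and non-early patients.  Each subject draws from its own generator
    seeded by ``(config.seed, subject_index)``, so adding or removing
    subjects does not perturb the others.
    """
    config.resolve_affected(atlas)  # fail fast on bad bundle labels
    config.resolve_weights(atlas)
    n_controls = config.n_controls if config.n_controls is not None else config.n_per_group
    n_early = config.n_per_group - config.n_per_group // 2
    plan: list[tuple[str, str, str]] = []
    for i in range(n_controls):
        plan.append((f"sub-C{i + 1:02d}", GROUP_CONTROL, STAGE_NONE))
    for i in range(config.n_per_group):
        stage = STAGE_EARLY if i < n_early else STAGE_NONEARLY
        plan.append((f"sub-P{i + 1:02d}", GROUP_PATIENT, stage))

    cohort = []
    for index, (sid, group, stage) in enumerate(plan):
        rng = np.random.default_rng(subject_seed(config.seed, index))
        cohort.append(
            simulate_subject(atlas, config, group, stage, rng, subject_id=sid)
        )
    return cohort


def null_config(config: CohortConfig) -> CohortConfig:
    """Copy of ``config`` with the group effect removed (multiplier 1)."""
    return replace(config, effect_multiplier=1.0)
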