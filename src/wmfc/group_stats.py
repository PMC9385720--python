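"""Two-group inference on bundle/region mCC with the 1/k correction.

Per-parcel two-sample t tests compare patients and controls; a parcel is
significant when its two-tailed p falls below 1/k, where k is the number of
parcels tested (1/48 for WM bundles, 1/82 for GM regions at the full
atlas).  This correction is a plain per-test threshold -- not a step-down
procedure -- and by linearity of expectation allows one false positive on
average regardless of the number of tests or their dependence.

Also provides the significant-voxel count-to-percentage reporting utility
for fixel-based structural summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    """Per-parcel t/p/significance for a two-group comparison."""

    parcel_labels: list[int]
    t: np.ndarray
    p: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    sem_a: np.ndarray
    sem_b: np.ndarray
    significant: np.ndarray
    alpha_used: float

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("p values must lie in [0, 1]")
        expected = self.p < self.alpha_used
        if not np.array_equal(np.asarray(self.significant, bool), expected):
            raise ValueError("significant flags must equal p < alpha_used")

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.significant))

    @property
    def significant_labels(self) -> list[int]:
        return [l for l, s in zip(self.parcel_labels, self.significant) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel": self.parcel_labels,
                "t": self.t,
                "p": self.p,
                "mean_a": self.mean_a,
                "mean_b": self.mean_b,
                "sem_a": self.sem_a,
                "sem_b": self.sem_b,
                "significant": np.asarray(self.significant, bool),
                "direction": np.where(self.t >= 0, "a>b", "a<b"),
            }
        )


@dataclass
class FixelCountTable:
    """Significant-voxel counts per structural measure and cohort."""

    measures: list[str]
    cohorts: list[str]
    counts: np.ndarray  # (n_measures, n_cohorts)
    totals: np.ndarray  # (n_cohorts,)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        if self.counts.shape != (len(self.measures), len(self.cohorts)):
            raise ValueError("counts shape must be (n_measures, n_cohorts)")
        if self.totals.shape != (len(self.cohorts),):
            raise ValueError("one total per cohort required")
        if (self.totals <= 0).any():
            raise ValueError("cohort totals must be positive")
        if (self.counts < 0).any() or (self.counts > self.totals).any():
            raise ValueError("counts must satisfy 0 <= count <= total")


def two_sample_t(
    x: np.ndarray, y: np.ndarray, equal_variance: bool = True
) -> tuple[float, float]:
    """Two-sample t test with two-tailed p.

    Student's pooled-variance t by default; Welch's unequal-variance
    variant with ``equal_variance=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) + y.var(ddof=1) == 0:
        raise ValueError("degenerate samples: zero variance in both groups")
    t, p = stats.ttest_ind(x, y, equal_var=equal_variance)
    return float(t), float(p)


def compare_parcels(
    mcc_a: np.ndarray,
    mcc_b: np.ndarray,
    alpha: float | None = None,
    parcel_labels: list[int] | None = None,
    equal_variance: bool = True,
) -> GroupComparison:
    """Parcel-wise two-sample t tests with the 1/k false-positive rule.

    ``mcc_a`` and ``mcc_b`` are (subjects x parcels) matrices of per-subject
    mCC values for groups A and B.  ``alpha`` defaults to 1/k with k the
    parcel count, the rule that bounds the expected number of false
    positives by one.
    """
    mcc_a = np.atleast_2d(np.asarray(mcc_a, dtype=float))
    mcc_b = np.atleast_2d(np.asarray(mcc_b, dtype=float))
    if mcc_a.shape[1] != mcc_b.shape[1]:
        raise ValueError(
            f"parcel dimension mismatch: {mcc_a.shape[1]} vs {mcc_b.shape[1]}"
        )
    if mcc_a.shape[0] < 2 or mcc_b.shape[0] < 2:
        raise ValueError("each group needs >= 2 subjects")
    k = mcc_a.shape[1]
    if alpha is None:
        alpha = 1.0 / k
    if parcel_labels is None:
        parcel_labels = list(range(1, k + 1))

    t = np.empty(k)
    p = np.empty(k)
    for j in range(k):
        t[j], p[j] = two_sample_t(mcc_a[:, j], mcc_b[:, j], equal_variance)
    return GroupComparison(
        parcel_labels=list(parcel_labels),
        t=t,
        p=p,
        mean_a=mcc_a.mean(axis=0),
        mean_b=mcc_b.mean(axis=0),
        sem_a=stats.sem(mcc_a, axis=0),
        sem_b=stats.sem(mcc_b, axis=0),
        significant=p < alpha,
        alpha_used=alpha,
    )


def summarize_fixel_counts(table: FixelCountTable) -> pd.DataFrame:
    """Convert significant-voxel counts to whole-number percentages.

    percentage = round(100 * count / total) to the nearest integer
    (half away from zero), per measure and cohort.
    """
    pct = np.floor(100.0 * table.counts / table.totals[None, :] + 0.5).astype(int)
    return pd.DataFrame(pct, index=table.measures, columns=table.cohorts)
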