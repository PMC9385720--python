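"""Stepwise multiple linear regression of clinical scores on bundle mCC.

Forward entry of the lowest-p candidate below ``p_enter``, backward removal
of any included predictor above ``p_remove``, iterated to a fixed point.
Partial p values come from the t test of the candidate's coefficient in the
augmented ordinary-least-squares fit, which for a single added predictor is
the textbook nested-model partial-F test.  Ties break deterministically by
candidate order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class RegressionResult:
    selected_predictors: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    r_squared: float
    steps: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        self.r_squared = min(self.r_squared, 1.0)

    def step_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _fit(y: np.ndarray, X: np.ndarray, cols: list[int]):
    design = sm.add_constant(X[:, cols], has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.OLS(y, design).fit()


def stepwise_regression(
    y: np.ndarray,
    X: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    feature_names: list[str] | None = None,
) -> RegressionResult:
    """Bidirectional stepwise ordinary least squares.

    Parameters
    ----------
    y : (n,) response (one clinical score).
    X : (n, k) candidate predictor matrix (bundle mCC features).
    p_enter, p_remove : entry/removal thresholds; ``p_enter < p_remove``
        guarantees a predictor just entered is not immediately removed.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, k = X.shape
    if y.size != n:
        raise ValueError("y length must match the number of rows of X")
    if y.std() == 0:
        raise ValueError("constant response: regression undefined")
    if not (0 < p_enter < p_remove < 1):
        raise ValueError("thresholds must satisfy 0 < p_enter < p_remove < 1")
    if feature_names is None:
        feature_names = [f"x{j + 1}" for j in range(k)]

    selected: list[int] = []
    steps: list[dict] = []
    max_steps = 2 * k  # entry strictly lowers RSS; removal set is bounded
    for _ in range(max_steps):
        changed = False

        # a numerically perfect fit leaves no residual variance: further
        # candidate p values would be 0/0 artifacts, so entry stops
        if selected and _fit(y, X, selected).rsquared >= 1.0 - 1e-12:
            break

        # forward entry: lowest partial p among candidates below p_enter
        best_p, best_j = np.inf, None
        for j in range(k):
            if j in selected:
                continue
            trial = selected + [j]
            if np.linalg.matrix_rank(
                np.column_stack([np.ones(n), X[:, trial]])
            ) < len(trial) + 1:
                warnings.warn(
                    f"candidate {feature_names[j]} is collinear with the "
                    f"current model; skipped", stacklevel=2,
                )
                continue
            fit = _fit(y, X, trial)
            p_j = float(fit.pvalues[-1])
            if np.isfinite(p_j) and p_j < best_p:
                best_p, best_j = p_j, j
        if best_j is not None and best_p < p_enter:
            selected.append(best_j)
            steps.append({"action": "enter", "predictor": feature_names[best_j],
                          "p": best_p})
            changed = True

        # backward removal: drop the worst included predictor above p_remove
        while selected:
            fit = _fit(y, X, selected)
            pvals = np.asarray(fit.pvalues[1:], dtype=float)
            worst = int(np.argmax(pvals))
            if pvals[worst] > p_remove:
                removed = selected.pop(worst)
                steps.append({"action": "remove",
                              "predictor": feature_names[removed],
                              "p": float(pvals[worst])})
                changed = True
            else:
                break

        if not changed:
            break

    if selected:
        fit = _fit(y, X, selected)
        coefficients = {"intercept": float(fit.params[0])}
        for name_idx, coef in zip(selected, fit.params[1:]):
            coefficients[feature_names[name_idx]] = float(coef)
        r2 = float(fit.rsquared)
    else:
        coefficients = {"intercept": float(y.mean())}
        r2 = 0.0

    return RegressionResult(
        selected_predictors=[feature_names[j] for j in selected],
        coefficients=coefficients,
        r_squared=r2,
        steps=steps,
    )
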