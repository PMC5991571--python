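"""Selection of task-related principal components.

A component is task-related when its temporal expression coefficient
(eigenvariate) correlates with the modeled hemodynamic response beyond a
Bonferroni-corrected critical value.  Testing every component of an
acquisition against the response at family-wise level alpha means each of the
n_frames correlations must individually reach alpha / (n_frames - 2) under
the t-test for a Pearson correlation with n_frames - 2 degrees of freedom.
For a 224-frame acquisition at alpha = .01 the critical |r| is 0.269; for an
84-frame acquisition it is 0.407.

Selection is sign-agnostic (|ecc| against the critical value): anticorrelated
networks are as task-related as correlated ones.  The signed ecc is retained
for weighting and interpretation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hrf import ModeledResponse
from .pca import ComponentSet

__all__ = [
    "EccRecord",
    "critical_r",
    "expression_correlation",
    "select_task_related",
    "selection_table",
]


@dataclass(frozen=True)
class EccRecord:
    """Correlation of one component's time course with the modeled response."""

    component: int
    ecc: float
    df: int
    critical_r: float
    significant: bool

    @property
    def abs_ecc(self) -> float:
        return abs(self.ecc)


def critical_r(alpha: float, n_tests: int, df: int) -> float:
    """Two-tailed critical Pearson correlation after Bonferroni correction.

    Inverts the t-test for a correlation coefficient,
    ``t = r * sqrt(df / (1 - r^2))``, at per-test level ``alpha / n_tests``:
    the returned r is the magnitude a sample correlation must exceed for
    two-tailed significance.  Monotone decreasing in ``df`` and increasing in
    ``n_tests``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if df < 3:
        raise ValueError("df must be >= 3")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n_tests), df)
    return float(t / np.sqrt(df + t * t))


def expression_correlation(eigenvariate: np.ndarray, response: ModeledResponse | np.ndarray) -> float:
    """Signed Pearson correlation (ecc) between a time course and the response.

    A zero-variance input yields NaN, which downstream selection flags as not
    significant.
    """
    y = response.values if isinstance(response, ModeledResponse) else np.asarray(response, float)
    x = np.asarray(eigenvariate, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("eigenvariate and response must share length >= 4")
    xs, ys = x.std(), y.std()
    if xs == 0.0 or ys == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def select_task_related(
    components: ComponentSet,
    response: ModeledResponse | np.ndarray,
    alpha: float = 0.01,
) -> list[EccRecord]:
    """Score every component's ecc and flag the task-related ones.

    The number of Bonferroni comparisons and the correlation degrees of
    freedom are both taken as ``n_frames - 2``, which reproduces the 0.269
    (224-frame) and 0.407 (84-frame) thresholds.
    """
    y = response.values if isinstance(response, ModeledResponse) else np.asarray(response, float)
    if y.size != components.n_frames:
        raise ValueError("response length must match the component frame count")
    df = components.n_frames - 2
    r_crit = critical_r(alpha, n_tests=df, df=df)
    records = []
    for i in range(len(components)):
        ecc = expression_correlation(components.eigenvariates[:, i], y)
        sig = bool(np.isfinite(ecc) and abs(ecc) > r_crit)
        records.append(
            EccRecord(component=i, ecc=ecc, df=df, critical_r=r_crit, significant=sig)
        )
    return records


def selection_table(records: list[EccRecord], acquisition=None) -> pd.DataFrame:
    """Selection report: one row per component."""
    df = pd.DataFrame(
        {
            "component": [r.component for r in records],
            "ecc": [r.ecc for r in records],
            "critical_r": [r.critical_r for r in records],
            "significant": [r.significant for r in records],
        }
    )
    if acquisition is not None:
        df.insert(0, "acquisition", str(acquisition))
    return df
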