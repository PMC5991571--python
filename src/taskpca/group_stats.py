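"""Group statistics on expression and volume correlation coefficients.

Condition differences in eccs are compared with the Mann-Whitney U test;
vccs of mean-image constituents with an unpaired pooled-variance t test;
pairs of correlations with the Fisher z transformation; constituent counts
with Fisher's exact test.  The joint (ecc, vcc) distributions of two
conditions are compared through Mahalanobis distances to the reference
condition's bivariate mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "mann_whitney",
    "unpaired_t",
    "fisher_compare_correlations",
    "fisher_exact_2x2",
    "mahalanobis_analysis",
    "MahalanobisResult",
]

#: exact Mann-Whitney enumeration below this group size, else normal
#: approximation with tie correction
EXACT_MW_MAX_N = 12


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U of group A, p).

    Exact when the smaller group has at most 12 observations and there are no
    ties; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    method = "exact" if min(a.size, b.size) <= EXACT_MW_MAX_N else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def unpaired_t(values_a, values_b) -> tuple[float, float]:
    """Unpaired two-tailed pooled-variance Student t test; returns (t, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0 and a.mean() != b.mean():
        raise ValueError("zero pooled variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def fisher_compare_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher z comparison of two independent correlations; returns (z, p).

    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))`` with a standard
    normal two-tailed p.  For volume correlations, pass n = effective_df + 3
    so that n - 3 equals the effective degrees of freedom.
    """
    for r in (r1, r2):
        if not abs(r) < 1.0:
            raise ValueError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("sample sizes must exceed 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("every margin must be positive")
    return float(stats.fisher_exact(t, alternative="two-sided").pvalue)


@dataclass
class MahalanobisResult:
    """Mahalanobis distances of two point clouds to a reference distribution."""

    mean: np.ndarray
    covariance: np.ndarray
    distances_reference: np.ndarray
    distances_other: np.ndarray
    p_value: float


def mahalanobis_analysis(points_reference, points_other) -> MahalanobisResult:
    """Compare two bivariate samples through the reference's Mahalanobis metric.

    Mean and unbiased covariance come from the reference group alone;
    ``d(x) = sqrt((x - mu)^T Sigma^-1 (x - mu))`` is evaluated for every point
    of both groups and the two distance samples are compared with the
    Mann-Whitney U test (p is NaN when either group is too small to compare).
    """
    ref = np.atleast_2d(np.asarray(points_reference, dtype=float))
    oth = np.atleast_2d(np.asarray(points_other, dtype=float))
    if ref.shape[0] < 3:
        raise ValueError("reference group needs at least 3 points")
    if ref.shape[1] != oth.shape[1]:
        raise ValueError("point clouds must share dimensionality")
    mu = ref.mean(axis=0)
    cov = np.cov(ref, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular reference covariance; regularize or add points"
        ) from err
    if np.linalg.cond(cov) > 1e12:
        raise ValueError("singular reference covariance; regularize or add points")

    def dist(x):
        d = x - mu
        return np.sqrt(np.einsum("ij,jk,ik->i", d, cov_inv, d))

    d_ref, d_oth = dist(ref), dist(oth)
    if min(d_ref.size, d_oth.size) >= 3:
        _, p = mann_whitney(d_ref, d_oth)
    else:
        p = float("nan")
    return MahalanobisResult(
        mean=mu,
        covariance=cov,
        distances_reference=d_ref,
        distances_other=d_oth,
        p_value=p,
    )
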