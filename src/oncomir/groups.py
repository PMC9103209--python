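"""Nonparametric group comparisons: Mann-Whitney U, Kruskal-Wallis with
Dunn post hoc, and median/IQR summaries.

These are the tests used to compare relative-expression levels and index
scores between patient groups (control, systemic, CNS-involved).  All are
rank-based and therefore invariant under strictly monotone transforms of
the data, so results are identical whether run on the raw 2^-dCt scale or
its log2.

The Mann-Whitney statistic relates to the ROC area through the exact
identity U / (n_x * n_y) = AUC(x-vs-y), with tied pairs credited 0.5 on
both sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "TestResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "median_iqr",
    "significance_stars",
]

#: Per-group-size cut-over from exact enumeration to the tie-corrected
#: normal approximation.  Exactness is cheap below this size.
EXACT_MAX_N = 8


@dataclass(frozen=True)
class GroupSummary:
    """Median with interquartile range, the panel's summary statistic."""

    label: str
    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError(
                f"quartile ordering violated: {self.q1}, {self.median}, {self.q3}"
            )


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    degenerate: bool = False


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U is computed from rank sums with mid-ranks on ties (the statistic is
    reported for the ``x`` sample).  The two-sided p-value uses exact
    enumeration when both groups have at most ``EXACT_MAX_N`` observations
    and the pooled sample is tie-free; otherwise the normal approximation
    with tie correction and continuity correction is used.

    A pooled-constant sample carries no ordering information: the result is
    U = n_x*n_y/2, p = 1 with ``degenerate=True`` rather than an error.
    """
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        return TestResult(
            statistic=x.size * y.size / 2.0, p_value=1.0,
            method="mann-whitney (degenerate)", degenerate=True,
        )
    has_ties = np.unique(pooled).size < pooled.size
    exact = x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="mann-whitney (exact)" if exact else "mann-whitney (asymptotic)",
    )


def kruskal_wallis(*groups) -> TestResult:
    """Kruskal-Wallis H test across two or more groups.

    H carries the usual tie correction; the p-value comes from the
    chi-squared distribution with k-1 degrees of freedom.  An all-constant
    pooled sample yields H = 0, p = 1 (degenerate flag set).
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    arrays = [_as_array(g, f"group {i}") for i, g in enumerate(groups)]
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise ValueError("kruskal_wallis requires a total of at least 3 observations")
    if np.ptp(pooled) == 0.0:
        return TestResult(0.0, 1.0, "kruskal-wallis (degenerate)", degenerate=True)
    h, p = stats.kruskal(*arrays)
    return TestResult(float(h), float(p), "kruskal-wallis")


def dunn_posthoc(groups: dict[str, "np.ndarray"], adjustment: str = "bonferroni") -> pd.DataFrame:
    """Dunn's post-hoc pairwise comparisons after Kruskal-Wallis.

    For each pair (i, j) the z statistic is the mean-rank difference scaled
    by the pooled, tie-corrected variance::

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j))
        T = sum(t^3 - t) / (12 (N - 1))   over tie groups of size t

    Parameters
    ----------
    groups
        Mapping of group label to 1-D sample; every group must be non-empty.
    adjustment
        ``"bonferroni"`` (default), ``"holm"`` or ``"none"``.

    Returns
    -------
    pandas.DataFrame
        One row per unordered pair with columns ``group_a, group_b, z,
        p_raw, p_adjusted``.
    """
    if adjustment not in {"bonferroni", "holm", "none"}:
        raise ValueError(f"unknown adjustment: {adjustment!r}")
    if len(groups) < 2:
        raise ValueError("dunn_posthoc requires at least 2 groups")
    labels = list(groups)
    arrays = [_as_array(groups[k], f"group {k!r}") for k in labels]

    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [a.size for a in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(labels))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0.0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z)) if se > 0.0 else 1.0
            rows.append((labels[i], labels[j], z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])

    m = len(df)
    if adjustment == "none":
        df["p_adjusted"] = df["p_raw"]
    elif adjustment == "bonferroni":
        df["p_adjusted"] = np.minimum(1.0, df["p_raw"] * m)
    else:  # holm
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["p_raw"], method="holm")[1]
    return df


def median_iqr(sample, label: str = "") -> GroupSummary:
    """Median and Tukey (inclusive-hinge) quartiles of a sample.

    The inclusive rule splits the sorted sample at the median, keeping the
    median in both halves when n is odd, and takes each half's median as
    the hinge — the convention of common clinical-stats software, fixed
    here so summaries are reproducible.
    """
    arr = np.sort(_as_array(sample, "sample"))
    n = arr.size
    med = float(np.median(arr))
    if n == 1:
        return GroupSummary(label, 1, med, med, med)
    half = (n + 1) // 2  # inclusive: odd n keeps the median in both halves
    q1 = float(np.median(arr[:half]))
    q3 = float(np.median(arr[n - half:]))
    return GroupSummary(label, n, med, q1, q3)


def significance_stars(p: float) -> str:
    """Figure-caption significance stars: *, **, *** at 0.05/0.01/0.001."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p out of range: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
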