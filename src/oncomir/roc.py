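"""ROC construction, AUC, and threshold-selection rules.

The classifier convention throughout is *positive call = score >= cut-off*,
matching the decision rule of :func:`oncomir.index.classify`.  Candidate
cut-offs are midpoints between consecutive distinct observed scores plus
infinite sentinels, which enumerates every decision-distinct threshold.

AUC is computed as the Mann-Whitney concordance probability (tied pairs
credited 0.5) and cross-checked internally against trapezoidal integration
of the curve; the two agree to floating-point precision by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RocCurve",
    "roc_curve",
    "auc",
    "select_threshold_closest_corner",
    "youden_index",
]


@dataclass(frozen=True)
class RocCurve:
    """An empirical ROC curve over all decision-distinct cut-offs.

    Sensitivity and specificity are stored in percent (0-100) to match the
    clinical reporting convention; the corner-distance rule operates on
    fractions internally.
    """

    cutoffs: np.ndarray          # descending; +inf first, -inf last
    sensitivity: np.ndarray      # percent, non-decreasing as cutoff drops
    specificity: np.ndarray      # percent, non-increasing as cutoff drops
    auc: float
    n_positive: int
    n_negative: int
    threshold: float | None = None
    threshold_sensitivity: float | None = None
    threshold_specificity: float | None = None
    threshold_youden: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC out of range: {self.auc}")

    @property
    def points(self) -> np.ndarray:
        """(n, 3) array of (cutoff, sensitivity %, specificity %)."""
        return np.column_stack([self.cutoffs, self.sensitivity, self.specificity])


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "ROC requires at least one positive and one negative sample "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    return scores, labels


def _concordance_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney concordance: P(score_pos > score_neg) + 0.5 P(tie).

    Rank-based O(n log n); identical to the U/(n_pos*n_neg) identity used
    by the rank tests in :mod:`oncomir.groups`.
    """
    from scipy.stats import rankdata

    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)  # mid-ranks on ties
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_curve(scores, labels) -> RocCurve:
    """Build the empirical ROC curve of ``scores`` against binary ``labels``.

    Parameters
    ----------
    scores
        Per-sample classifier scores (finite floats).
    labels
        Truth labels; truthy = positive class (CNS-involved).

    Returns
    -------
    RocCurve
        One point per candidate cut-off; endpoints (sens 100, spec 0) and
        (sens 0, spec 100) are always present via the infinite sentinels.
    """
    scores, labels = _validate(scores, labels)
    pos = scores[labels]
    neg = scores[~labels]

    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    # Descending cut-offs: +inf (call nothing) .. -inf (call everything).
    cutoffs = np.concatenate([[np.inf], distinct[::-1], mids[::-1], [-np.inf]])
    cutoffs = np.unique(cutoffs)[::-1]

    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    # count(pos >= c) = n_pos - #(pos < c); count(neg < c) via searchsorted
    sens = (pos.size - np.searchsorted(pos_sorted, cutoffs, side="left")) / pos.size * 100.0
    spec = np.searchsorted(neg_sorted, cutoffs, side="left") / neg.size * 100.0

    auc_conc = _concordance_auc(pos, neg)
    # Internal cross-check: trapezoid over (FPR, TPR) must agree.
    fpr = 1.0 - spec / 100.0
    tpr = sens / 100.0
    auc_trap = float(np.trapezoid(tpr, fpr))
    if abs(auc_trap - auc_conc) > 1e-12:
        raise AssertionError(
            f"trapezoid AUC {auc_trap!r} != concordance AUC {auc_conc!r}"
        )

    return RocCurve(
        cutoffs=cutoffs,
        sensitivity=sens,
        specificity=spec,
        auc=auc_conc,
        n_positive=pos.size,
        n_negative=neg.size,
    )


def auc(scores, labels) -> float:
    """Area under the ROC curve in [0, 1] (ties credited 0.5)."""
    scores, labels = _validate(scores, labels)
    return _concordance_auc(scores[labels], scores[~labels])


def youden_index(sensitivity_pct: float, specificity_pct: float) -> float:
    """Youden index in percentage points: sensitivity% + specificity% - 100.

    Ranges over [-100, 100]; 0 is the chance line.
    """
    if not (0.0 <= sensitivity_pct <= 100.0 and 0.0 <= specificity_pct <= 100.0):
        raise ValueError(
            "sensitivity and specificity must be percentages in [0, 100], got "
            f"({sensitivity_pct}, {specificity_pct})"
        )
    return sensitivity_pct + specificity_pct - 100.0


def select_threshold_closest_corner(curve: RocCurve) -> RocCurve:
    """Select the cut-off closest to the perfect-classifier corner.

    Minimizes (1 - sensitivity)^2 + (specificity - 1)^2 with sensitivity and
    specificity as fractions.  Ties are broken toward the higher Youden
    index, then toward higher specificity; this rule coincides with the
    maximal Youden index on most well-behaved curves.

    Returns a copy of ``curve`` with the threshold fields populated.
    Infinite sentinel cut-offs are never selected when a finite cut-off
    achieves the same distance.
    """
    sens = curve.sensitivity / 100.0
    spec = curve.specificity / 100.0
    dist = (1.0 - sens) ** 2 + (spec - 1.0) ** 2
    youden = curve.sensitivity + curve.specificity - 100.0

    # Lexicographic: distance asc, youden desc, specificity desc, finite first.
    order = np.lexsort(
        (~np.isfinite(curve.cutoffs), -curve.specificity, -youden, dist)
    )
    best = order[0]
    return RocCurve(
        cutoffs=curve.cutoffs,
        sensitivity=curve.sensitivity,
        specificity=curve.specificity,
        auc=curve.auc,
        n_positive=curve.n_positive,
        n_negative=curve.n_negative,
        threshold=float(curve.cutoffs[best]),
        threshold_sensitivity=float(curve.sensitivity[best]),
        threshold_specificity=float(curve.specificity[best]),
        threshold_youden=float(youden[best]),
    )
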