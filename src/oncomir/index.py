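"""The oncomiR index: a weighted linear combination of equalized miRNA
relative-expression values, with a logistic link for CNS-involvement
probability.

For a panel of oncogenic miRNAs with non-negative weights, the index of a
sample is::

    score = sum_i coefficient_i * abundance_i

and the probability of CNS involvement is the logistic transform::

    P(CNS) = 1 / (1 + exp(X - score))

where ``X`` is the intercept.  Coefficients are fitted by maximizing the
difference of average CNS probabilities between the CNS-involved and the
systemic class (see :func:`fit_coefficients`); a miRNA whose fitted
coefficient is zero is dropped from the panel.

Eight published presets (four B-NHL subtypes x two compartments) ship with
the package, each with the coefficient set and the ROC-selected decision
threshold on the raw index scale along with its log2.  The presets do not
publish an intercept, so :func:`cns_probability` on a preset requires ``X``
to be supplied explicitly; the linear score and threshold-based
classification are always available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "IndexModel",
    "FitResult",
    "TrajectoryAlert",
    "load_presets",
    "get_preset",
    "preset_names",
    "compute_index",
    "score_table",
    "cns_probability",
    "classify",
    "fit_coefficients",
    "flag_rising_trajectory",
]

#: Maximum allowed discrepancy between log2(threshold_raw) and a stored
#: (printed, 2-decimal) threshold_log2.
LOG2_THRESHOLD_TOL = 0.005

#: Fitted coefficients at or below this are treated as exactly zero and the
#: miRNA is excluded from the panel.
ZERO_COEF_TOL = 1e-6


@dataclass(frozen=True)
class IndexModel:
    """A named oncomiR panel with weights, optional intercept and threshold."""

    name: str
    coefficients: dict[str, float]
    compartment: str | None = None
    intercept: float | None = None
    threshold_raw: float | None = None
    threshold_log2: float | None = None

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("index model needs at least one miRNA with weight > 0")
        for mirna, coef in self.coefficients.items():
            if not np.isfinite(coef) or coef < 0:
                raise ValueError(f"coefficient for {mirna} must be finite and >= 0")
            if coef == 0:
                raise ValueError(
                    f"{mirna} has coefficient 0 and must be excluded from the panel"
                )
        if self.threshold_raw is not None:
            if self.threshold_raw <= 0:
                raise ValueError("threshold_raw must be positive")
            log2_thr = float(np.log2(self.threshold_raw))
            stored = self.threshold_log2
            if stored is None:
                object.__setattr__(self, "threshold_log2", log2_thr)
            elif abs(stored - log2_thr) > LOG2_THRESHOLD_TOL:
                raise ValueError(
                    f"threshold_log2 {stored} inconsistent with "
                    f"log2({self.threshold_raw}) = {log2_thr:.4f}"
                )
        elif self.threshold_log2 is not None:
            object.__setattr__(self, "threshold_raw", float(2.0 ** self.threshold_log2))

    @property
    def panel(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def with_threshold(self, threshold_raw: float) -> "IndexModel":
        return replace(self, threshold_raw=float(threshold_raw), threshold_log2=None)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "compartment": self.compartment,
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "threshold_raw": self.threshold_raw,
            "threshold_log2": self.threshold_log2,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "IndexModel":
        return cls(
            name=d["name"],
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            compartment=d.get("compartment"),
            intercept=d.get("intercept"),
            threshold_raw=d.get("threshold_raw"),
            threshold_log2=d.get("threshold_log2"),
        )


def load_presets() -> dict[str, IndexModel]:
    """Load the published preset registry (immutable source JSON)."""
    raw = json.loads(
        resources.files("oncomir.data").joinpath("presets.json").read_text()
    )
    models = {}
    for entry in raw["presets"]:
        models[entry["name"]] = IndexModel(
            name=entry["name"],
            coefficients=dict(entry["coefficients"]),
            compartment=entry["compartment"],
            threshold_raw=entry["threshold_raw"],
            threshold_log2=entry["threshold_log2"],
        )
    return models


def preset_names() -> list[str]:
    return list(load_presets())


def get_preset(name: str) -> IndexModel:
    presets = load_presets()
    try:
        return presets[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        ) from None


def _abundance_vector(model: IndexModel, abundances: Mapping[str, float]) -> np.ndarray:
    vals = []
    for mirna in model.panel:
        if mirna not in abundances:
            raise ValueError(f"panel miRNA {mirna!r} missing from abundances")
        v = float(abundances[mirna])
        if not np.isfinite(v):
            raise ValueError(f"panel miRNA {mirna!r} has a missing/non-finite value")
        vals.append(v)
    return np.array(vals)


def compute_index(model: IndexModel, abundances: Mapping[str, float]) -> float:
    """Weighted index score: sum of coefficient_i * abundance_i (>= 0)."""
    coefs = np.array([model.coefficients[m] for m in model.panel])
    return float(coefs @ _abundance_vector(model, abundances))


def score_table(model: IndexModel, values: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`compute_index` over an expression matrix.

    Rows with a missing panel value get NaN (no imputation); a panel miRNA
    absent from the columns is an error.
    """
    missing = [m for m in model.panel if m not in values.columns]
    if missing:
        raise ValueError(f"panel miRNAs missing from expression table: {missing}")
    coefs = pd.Series(model.coefficients)
    sub = values[list(model.panel)]
    scores = sub.mul(coefs, axis=1).sum(axis=1, skipna=False)
    return scores.rename(f"{model.name}_index")


def cns_probability(
    model: IndexModel, abundances: Mapping[str, float], intercept: float | None = None
) -> float:
    """Logistic CNS-involvement probability 1/(1 + exp(X - score)).

    Strictly increasing in the score, equal to 0.5 exactly at score = X.
    The intercept comes from the model or the ``intercept`` argument; the
    published presets carry none, so it must be supplied for them.
    """
    x = intercept if intercept is not None else model.intercept
    if x is None or not np.isfinite(x):
        raise ValueError(
            f"model {model.name!r} has no intercept; supply X explicitly"
        )
    from scipy.special import expit

    score = compute_index(model, abundances)
    return float(expit(score - x))


def classify(
    model: IndexModel, abundances: Mapping[str, float] | None = None, score: float | None = None
) -> tuple[bool, float]:
    """CNS-involvement call at the model threshold.

    Positive iff score >= threshold_raw (the threshold itself is called
    positive: published cut-offs are cut-offs *for* involvement).  Returns
    ``(positive, score)``.
    """
    if model.threshold_raw is None:
        raise ValueError(f"model {model.name!r} has no decision threshold")
    if score is None:
        if abundances is None:
            raise ValueError("either abundances or a precomputed score is required")
        score = compute_index(model, abundances)
    return bool(score >= model.threshold_raw), float(score)


# ---------------------------------------------------------------------------
# Coefficient fitting


@dataclass(frozen=True)
class FitResult:
    model: IndexModel
    objective: float                    # mean P(CNS|pos) - mean P(CNS|neg)
    dropped: tuple[str, ...]            # miRNAs removed (coefficient -> 0)
    n_starts: int
    objective_trace: tuple[float, ...]  # best objective per start, sorted desc


def _class_separation(theta, a_pos, a_neg):
    """Objective and gradient: mean sigmoid(score-X) difference between classes."""
    coefs, x = theta[:-1], theta[-1]
    from scipy.special import expit

    def side(a):
        s = a @ coefs - x
        p = expit(s)
        w = p * (1.0 - p)
        grad_c = (a * w[:, None]).mean(axis=0)
        grad_x = -w.mean()
        return p.mean(), np.append(grad_c, grad_x)
    f_pos, g_pos = side(a_pos)
    f_neg, g_neg = side(a_neg)
    return f_pos - f_neg, g_pos - g_neg


def fit_coefficients(
    values: pd.DataFrame,
    labels,
    panel: Sequence[str] | None = None,
    coef_bounds: tuple[float, float] = (0.0, 10.0),
    intercept_bounds: tuple[float, float] = (-20.0, 20.0),
    n_starts: int = 16,
    seed: int = 0,
    drop_tol: float = 0.02,
    name: str = "fitted",
    compartment: str | None = None,
) -> FitResult:
    """Fit index coefficients by maximizing the class-probability gap.

    The objective is mean P(CNS involvement) over CNS-positive samples
    minus the mean over systemic samples, with P the logistic link of the
    weighted score.  The objective is scale-degenerate — inflating all
    coefficients and the intercept together approaches a 0/1 step — so a
    bounded box is required for a well-posed problem: coefficients in
    ``coef_bounds`` (default [0, 10]), intercept in ``intercept_bounds``
    (default [-20, 20]).

    Optimization is a deterministic multi-start bounded quasi-Newton
    search from a seeded set of starting points.  Among near-equal optima
    (objective within 1e-6 of the best) the solution with the smallest
    coefficient L2 norm wins, for reproducibility.

    The fit then sparsifies by backward elimination: a miRNA is assigned
    coefficient 0 (and excluded from the panel) when refitting without it
    costs less than ``drop_tol`` of the objective.  The probability gap is
    estimated from finite samples, so contributions below its sampling
    noise floor — roughly 2/sqrt(n) per class, hence the 0.02 default at
    cohort scale — are indistinguishable from overfitting.  The last
    remaining miRNA is never eliminated; on uninformative data the
    returned objective is near 0 and no coefficient is stable.
    Coefficients within ``ZERO_COEF_TOL`` of zero likewise drop their
    miRNA.

    Parameters
    ----------
    values
        Expression matrix (samples x miRNAs), strictly positive abundances.
    labels
        Boolean per sample; True = CNS-involved, False = systemic.
    panel
        Candidate miRNAs (default: all columns of ``values``).
    """
    if coef_bounds is None or intercept_bounds is None:
        raise ValueError(
            "unbounded fitting is not identifiable: scaling all coefficients "
            "and the intercept together inflates the objective without limit; "
            "supply finite bounds"
        )
    panel = list(panel if panel is not None else values.columns)
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("need at least 2 samples in each class")
    a = values[panel].to_numpy(dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a <= 0):
        raise ValueError("abundances must be finite and strictly positive")
    a_pos, a_neg = a[labels], a[~labels]

    lo, hi = coef_bounds
    xlo, xhi = intercept_bounds
    rng = np.random.default_rng(seed)

    def multistart(cols: list[int], n_st: int) -> tuple[float, np.ndarray, list[float]]:
        """Best (objective, theta) over seeded starts for a column subset;
        ties go to the smallest coefficient norm."""
        m = len(cols)
        ap, an = a_pos[:, cols], a_neg[:, cols]
        bounds = [(lo, hi)] * m + [(xlo, xhi)]
        starts = [np.append(np.full(m, (lo + hi) / 2), 0.0),
                  np.append(np.full(m, lo + 0.1 * (hi - lo)), 0.0)]
        while len(starts) < n_st:
            c = rng.uniform(lo, hi, size=m)
            x0 = rng.uniform(max(xlo, -10.0), min(xhi, 10.0))
            starts.append(np.append(c, x0))

        def neg(theta):
            f, g = _class_separation(theta, ap, an)
            return -f, -g

        cands = []
        for theta0 in starts[:n_st]:
            res = minimize(neg, theta0, jac=True, method="L-BFGS-B", bounds=bounds)
            cands.append((float(-res.fun), res.x))
        best = max(f for f, _ in cands)
        near = [(f, th) for f, th in cands if f >= best - 1e-6]
        near.sort(key=lambda ft: (np.linalg.norm(ft[1][:-1]), -ft[0]))
        obj, theta = near[0]
        return obj, theta, [f for f, _ in cands]

    active = list(range(len(panel)))
    obj, theta, trace = multistart(active, n_starts)

    # Backward elimination: zero out panel members whose removal costs
    # less than drop_tol of the probability gap.
    while len(active) > 1:
        order = np.argsort(theta[:-1])  # cheapest-looking candidates first
        for pos in order:
            reduced = active[:pos] + active[pos + 1:]
            r_obj, r_theta, _ = multistart(reduced, max(4, n_starts // 2))
            if r_obj >= obj - drop_tol:
                active, obj, theta = reduced, r_obj, r_theta
                break
        else:
            break

    coefs = {panel[i]: float(c) for i, c in zip(active, theta[:-1])}
    kept = {mi: c for mi, c in coefs.items() if c > ZERO_COEF_TOL}
    if not kept:  # last survivor pinned at ~0: keep it, data are uninformative
        kept = {panel[active[0]]: max(float(theta[0]), ZERO_COEF_TOL * 10)}
    dropped = tuple(mi for mi in panel if mi not in kept)
    model = IndexModel(
        name=name, coefficients=kept, compartment=compartment,
        intercept=float(theta[-1]),
    )
    return FitResult(
        model=model, objective=obj, dropped=dropped,
        n_starts=n_starts, objective_trace=tuple(sorted(trace, reverse=True)),
    )


def split_train_test(
    values: pd.DataFrame, labels, test_fraction: float = 0.3, seed: int = 0
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame, np.ndarray]:
    """Seeded stratified train/test split for out-of-sample evaluation.

    Splits within each class so both partitions keep the class mix.
    Returns ``(values_train, labels_train, values_test, labels_test)``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(len(values), dtype=bool)
    for cls in (True, False):
        idx = np.flatnonzero(labels == cls)
        n_test = max(1, int(round(test_fraction * idx.size)))
        test_mask[rng.choice(idx, size=n_test, replace=False)] = True
    return (values.iloc[~test_mask], labels[~test_mask],
            values.iloc[test_mask], labels[test_mask])


# ---------------------------------------------------------------------------
# Longitudinal monitoring


@dataclass(frozen=True)
class TrajectoryAlert:
    alert: bool
    onset_time: float | None = None
    fold_rise: float | None = None


def flag_rising_trajectory(
    times: Sequence[float],
    scores: Sequence[float],
    k: int = 2,
    rel_increase: float = 1.5,
) -> TrajectoryAlert:
    """Flag a serially-sampled patient whose index is rising.

    An alert fires when some window of ``k`` consecutive strictly
    increasing steps achieves a total fold-rise of at least
    ``rel_increase`` from the window's start.  The onset is the time of
    the first point of the earliest such window.  Defaults (k = 2 rises,
    1.5x total) reflect the observation that the index climbs over the
    1-4 months preceding a CNS relapse.
    """
    times = np.asarray(times, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if times.shape != scores.shape or times.ndim != 1:
        raise ValueError("times and scores must be 1-D and equal-length")
    if times.size < k + 1:
        raise ValueError(f"need at least k+1 = {k + 1} timepoints, got {times.size}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if np.any(scores < 0):
        raise ValueError("index scores must be non-negative")

    for start in range(times.size - k):
        window = scores[start : start + k + 1]
        if np.all(np.diff(window) > 0):
            base, top = window[0], window[-1]
            fold = np.inf if base == 0 else top / base
            if fold >= rel_increase:
                return TrajectoryAlert(True, float(times[start]), float(fold))
    return TrajectoryAlert(False)
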