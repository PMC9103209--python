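"""Index-based risk stratification: Kaplan-Meier estimates, cumulative
incidence of CNS relapse, log-rank tests, univariate Cox hazard ratios,
and the combined clinical-index + oncomiR risk model.

Time is measured in months from diagnosis.  Cumulative incidence of CNS
relapse is estimated as 1 - KM(t) — ignoring death as a competing risk,
which matches the published treatment — with an Aalen-Johansen
competing-risk estimator available behind a flag for sensitivity
analysis.  Cox models use Efron tie handling and likelihood-ratio
p-values.

Estimation is delegated to ``lifelines`` (KaplanMeierFitter, CoxPHFitter,
logrank_test, AalenJohansenFitter); this module owns the stratification
rules, the incidence/horizon conventions, and the result surfaces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import AalenJohansenFitter, CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "KaplanMeierResult",
    "LogRankResult",
    "CoxResult",
    "kaplan_meier",
    "cumulative_incidence_at",
    "logrank_test",
    "cox_univariate",
    "stratify_by_index",
    "combined_risk_strata",
    "risk_table",
]


@dataclass(frozen=True)
class KaplanMeierResult:
    """Product-limit survival estimate S(t) as a right-continuous step function."""

    times: np.ndarray          # step times, ascending, starting at 0
    survival: np.ndarray       # S(t) at each step, S(0) = 1
    n: int
    n_events: int

    def at(self, t: float) -> float:
        """S(t) using the last step at or before ``t``."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    @property
    def max_time(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float          # log-likelihood ratio test vs the null model
    log_hr: float
    se_log_hr: float
    n: int
    n_events: int
    flagged: str = ""


def _check_times(times) -> np.ndarray:
    arr = np.asarray(times, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one subject")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("times must be finite and non-negative")
    return arr


def kaplan_meier(times, events) -> KaplanMeierResult:
    """Kaplan-Meier product-limit estimator.

    Parameters
    ----------
    times
        Months to event or censoring (non-negative).
    events
        1/True where the event occurred, 0/False where censored.
    """
    times = _check_times(times)
    events = np.asarray(events, dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    t = sf.index.to_numpy(dtype=float)
    s = sf.iloc[:, 0].to_numpy(dtype=float)
    if t[0] != 0.0:
        t = np.concatenate([[0.0], t])
        s = np.concatenate([[1.0], s])
    return KaplanMeierResult(times=t, survival=s, n=times.size,
                             n_events=int(events.sum()))


def cumulative_incidence_at(
    times, events, horizon: float, competing_risk: bool = False,
    death_times=None, death_events=None,
) -> tuple[float, bool]:
    """Cumulative event incidence at ``horizon`` months, in percent.

    Default is the published convention 1 - KM(horizon).  With
    ``competing_risk=True`` (and death columns supplied) the
    Aalen-Johansen estimator treats death before relapse as a competing
    event instead of censoring.

    Returns ``(incidence_percent, extrapolated)``; ``extrapolated`` is True
    when the horizon exceeds the last observed follow-up time, in which
    case the last available estimate is carried forward.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    times = _check_times(times)
    events = np.asarray(events, dtype=bool)
    extrapolated = horizon > float(times.max())
    if competing_risk:
        if death_times is None or death_events is None:
            raise ValueError("competing-risk estimate needs death times and events")
        death_times = _check_times(death_times)
        death_events = np.asarray(death_events, dtype=bool)
        # event code 1 = relapse, 2 = prior death, 0 = censored
        first = np.where(events & (times <= np.where(death_events, death_times, np.inf)), 1, 0)
        first = np.where((first == 0) & death_events & (death_times <= times), 2, first)
        t = np.where(first == 2, death_times, times)
        ajf = AalenJohansenFitter(calculate_variance=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ajf.fit(t, first, event_of_interest=1)
        ci = ajf.cumulative_density_
        idx = ci.index.to_numpy(dtype=float)
        vals = ci.iloc[:, 0].to_numpy(dtype=float)
        pos = np.searchsorted(idx, horizon, side="right") - 1
        return float(vals[max(pos, 0)] * 100.0), extrapolated
    km = kaplan_meier(times, events)
    return (1.0 - km.at(horizon)) * 100.0, extrapolated


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank (Mantel-Cox) test, 1 degree of freedom.

    With no events in either stratum there is nothing to compare: returns
    chi2 = 0, p = 1 with the degenerate flag set.
    """
    times_a, times_b = _check_times(times_a), _check_times(times_b)
    events_a = np.asarray(events_a, dtype=bool)
    events_b = np.asarray(events_b, dtype=bool)
    if events_a.sum() + events_b.sum() == 0:
        return LogRankResult(0.0, 1.0, degenerate=True)
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return LogRankResult(float(res.test_statistic), float(res.p_value))


def cox_univariate(times, events, covariate) -> CoxResult:
    """Univariate Cox proportional-hazards model.

    Partial-likelihood Newton fit with Efron tie handling; the hazard
    ratio is per unit of ``covariate`` (so for a 0/1 stratum indicator it
    is the high-vs-low ratio), the 95% CI comes from the observed
    information, and the p-value from the likelihood-ratio test against
    the null model.

    Monotone likelihood (e.g. complete separation of event order) is
    reported via ``flagged`` rather than raised.
    """
    times = _check_times(times)
    events = np.asarray(events, dtype=bool)
    cov = np.asarray(covariate, dtype=float)
    if events.sum() < 1:
        raise ValueError("need at least one event")
    if np.ptp(cov) == 0:
        raise ValueError("covariate has no variation")
    df = pd.DataFrame({"time": times, "event": events.astype(int), "x": cov})
    cph = CoxPHFitter()
    flagged = ""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="time", event_col="event")
        for w in caught:
            if "convergence" in str(w.message).lower() or "separation" in str(w.message).lower():
                flagged = str(w.message)
    beta = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    lrt = cph.log_likelihood_ratio_test()
    return CoxResult(
        hazard_ratio=float(np.exp(beta)),
        ci_lower=float(np.exp(beta - 1.959963984540054 * se)),
        ci_upper=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(lrt.p_value),
        log_hr=beta,
        se_log_hr=se,
        n=times.size,
        n_events=int(events.sum()),
        flagged=flagged,
    )


def stratify_by_index(scores: pd.Series, cutoff: float) -> pd.DataFrame:
    """High/low oncomiR stratification at a cut-off (high iff score >= cutoff).

    Missing scores exclude the patient (count reported in the attrs).
    Returns a frame indexed like the non-missing scores with columns
    ``score`` and ``stratum`` ("high"/"low").
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    scores = scores.astype(float)
    n_missing = int(scores.isna().sum())
    kept = scores.dropna()
    out = pd.DataFrame({
        "score": kept,
        "stratum": np.where(kept >= cutoff, "high", "low"),
    })
    out.attrs["n_excluded_missing"] = n_missing
    out.attrs["fraction_high"] = float((out["stratum"] == "high").mean()) if len(out) else np.nan
    return out


def combined_risk_strata(oncomir_high, cnsipi_high) -> pd.Series:
    """Combined oncomiR + clinical-index risk groups.

    ``both risks`` = high oncomiR and high CNS-IPI; ``one risk`` = exactly
    one of the two; ``no risk`` = neither.  Patients with a missing label
    are excluded (NaN in the output).
    """
    a = pd.Series(oncomir_high)
    b = pd.Series(cnsipi_high)
    if len(a) != len(b):
        raise ValueError("label vectors must align")
    out = pd.Series(index=a.index, dtype=object)
    valid = a.notna() & b.notna()
    av = a[valid].astype(bool)
    bv = b[valid].astype(bool)
    out[valid] = np.select(
        [av & bv, av ^ bv], ["both risks", "one risk"], default="no risk"
    )
    out.attrs["n_excluded_missing"] = int((~valid).sum())
    return out


def risk_table(
    data: pd.DataFrame,
    stratum_col: str,
    time_col: str = "time",
    event_col: str = "event",
    horizon: float = 48.0,
    reference: str | None = None,
) -> pd.DataFrame:
    """Per-stratum risk summary: n, % of cohort, cumulative incidence at
    the horizon (default 4 years), and hazard ratio vs the reference
    stratum with 95% CI and log-rank p.

    The reference stratum defaults to the one with the lowest event rate.
    """
    strata = data[stratum_col].dropna().unique().tolist()
    if reference is None:
        rates = {
            s: data.loc[data[stratum_col] == s, event_col].mean() for s in strata
        }
        reference = min(rates, key=rates.get)
    ref = data[data[stratum_col] == reference]
    rows = []
    total = len(data.dropna(subset=[stratum_col]))
    for s in strata:
        sub = data[data[stratum_col] == s]
        inc, _ = cumulative_incidence_at(sub[time_col], sub[event_col], horizon)
        if s == reference or sub[event_col].sum() + ref[event_col].sum() == 0:
            hr = ci_lo = ci_hi = p = np.nan
            if s == reference:
                hr, p = 1.0, np.nan
        else:
            pooled = pd.concat([sub, ref])
            indicator = np.concatenate([np.ones(len(sub)), np.zeros(len(ref))])
            try:
                cox = cox_univariate(pooled[time_col], pooled[event_col], indicator)
                hr, ci_lo, ci_hi, p = (cox.hazard_ratio, cox.ci_lower,
                                       cox.ci_upper, cox.p_value)
            except Exception:
                hr = ci_lo = ci_hi = p = np.nan
        rows.append((s, len(sub), 100.0 * len(sub) / total, inc, hr, ci_lo, ci_hi, p))
    return pd.DataFrame(
        rows,
        columns=["stratum", "n", "percent", f"incidence_{horizon:g}mo",
                 "hazard_ratio", "ci_lower", "ci_upper", "p_value"],
    ).set_index("stratum")
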