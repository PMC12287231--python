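"""Censored-data machinery: Kaplan-Meier, log-rank, Cox PH, risk prediction,
and Harrell's concordance.

Times are months throughout the package.  The Cox fitter maximises the exact
partial likelihood (Efron tie correction by default, Breslow optional) by
Newton-Raphson with step-halving; the baseline cumulative hazard is the
Breslow estimator at covariates equal to zero, so
``P(event by t | x) = 1 - exp(-H0(t) * exp(x @ beta))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import coxph
from .coxph import SingularDesignError  # noqa: F401  (re-exported)

__all__ = [
    "SurvivalCurve",
    "kaplan_meier",
    "LogrankResult",
    "logrank_test",
    "CoxFit",
    "cox_fit",
    "predict_event_prob",
    "harrell_c",
]


@dataclass
class SurvivalCurve:
    """Product-limit estimate with Greenwood variance and log-log bands.

    ``median_survival`` is the earliest event time with survival <= 0.5 and
    NaN when the curve never reaches 0.5 ("not reached").
    """

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival_prob: np.ndarray
    greenwood_se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median_survival: float
    median_ci: tuple[float, float]
    n: int

    def survival_at(self, t) -> np.ndarray | float:
        """Step-function evaluation; S = 1 before the first event time."""
        t = np.asarray(t, dtype=float)
        if self.event_times.size == 0:
            s = np.ones_like(t)
        else:
            idx = np.searchsorted(self.event_times, t, side="right") - 1
            s = np.where(idx < 0, 1.0, self.survival_prob[np.maximum(idx, 0)])
        return float(s) if s.ndim == 0 else s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "at_risk": self.at_risk,
            "n_events": self.n_events,
            "survival": self.survival_prob,
            "se": self.greenwood_se,
            "lower": self.ci_lower,
            "upper": self.ci_upper,
        })


def kaplan_meier(times, events, alpha: float = 0.05) -> SurvivalCurve:
    """Kaplan-Meier estimate of the survival function.

    Confidence bands use the log(-log) (exponential Greenwood) transform,
    and the median CI is read off the band crossings of 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty survival data")
    if times.shape != events.shape:
        raise ValueError("times and events must have the same length")
    if np.any(times < 0) or not np.all(np.isfinite(times)):
        raise ValueError("times must be finite and non-negative")
    n = times.size
    ts = np.sort(times)
    ev_times = times[events == 1]
    ut, d = np.unique(ev_times, return_counts=True)
    at_risk = n - np.searchsorted(ts, ut, side="left")
    frac = 1.0 - d / at_risk
    S = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = d / (at_risk * (at_risk - d))
        gw_cum = np.cumsum(gw_terms)
        se = S * np.sqrt(gw_cum)
        se = np.where(S == 0, 0.0, se)
        # exponential-Greenwood (log-log) bands
        se_cll = np.sqrt(gw_cum) / np.abs(np.log(S))
        z = stats.norm.ppf(1 - alpha / 2)
        lower = S ** np.exp(z * se_cll)
        upper = S ** np.exp(-z * se_cll)
    interior = (S > 0) & (S < 1)
    lower = np.where(interior, lower, S)
    upper = np.where(interior, upper, S)

    def _first_crossing(curve):
        hit = np.flatnonzero(curve <= 0.5)
        return float(ut[hit[0]]) if hit.size else float("nan")

    median = _first_crossing(S)
    median_ci = (_first_crossing(lower), _first_crossing(upper))
    return SurvivalCurve(
        event_times=ut, at_risk=at_risk, n_events=d, survival_prob=S,
        greenwood_se=se, ci_lower=lower, ci_upper=upper,
        median_survival=median, median_ci=median_ci, n=n,
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p_value: float
    df: int


def logrank_test(times, events, groups) -> LogrankResult:
    """Two-sided log-rank test across two or more groups."""
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("log-rank test requires at least two groups")
    res = multivariate_logrank_test(times, groups, events)
    return LogrankResult(statistic=float(res.test_statistic),
                         p_value=float(res.p_value),
                         df=int(labels.size - 1))


@dataclass
class CoxFit:
    """Fitted Cox proportional-hazards model.

    ``baseline_times``/``baseline_cumhaz`` are the knots of the Breslow
    baseline cumulative hazard at covariates = 0.
    """

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik_null: float
    loglik_fit: float
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    ties_method: str
    n: int
    n_events: int
    converged: bool
    flag: str | None = None
    design_info: dict | None = None

    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def confidence_intervals(self, alpha: float = 0.05):
        z = stats.norm.ppf(1 - alpha / 2)
        return np.exp(self.coef - z * self.se), np.exp(self.coef + z * self.se)

    def linear_predictor(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return X @ self.coef

    def summary(self) -> pd.DataFrame:
        lo, hi = self.confidence_intervals()
        return pd.DataFrame({
            "coef": self.coef, "hr": np.exp(self.coef), "se": self.se,
            "hr_lower": lo, "hr_upper": hi, "z": self.z, "p": self.p,
        }, index=list(self.names))


def cox_fit(X, times, events, ties: str = "efron", names=None,
            tol: float = 1e-8, max_iter: int = 100,
            initial_beta=None) -> CoxFit:
    """Fit a Cox proportional-hazards model.

    Parameters
    ----------
    X : (n, k) array or DataFrame of covariates (no constant columns).
    ties : "efron" (default) or "breslow".
    initial_beta : optional warm start (e.g. the full-data coefficients
        inside a bootstrap loop); when given, ``loglik_null`` is skipped
        and returned as NaN.

    Raises
    ------
    ValueError
        For empty/constant designs or data with no events.
    SingularDesignError
        When the information matrix is singular.
    """
    if isinstance(X, pd.DataFrame):
        if names is None:
            names = tuple(map(str, X.columns))
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    if X.shape[1] == 0:
        raise ValueError("design matrix has no columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    if np.any(X.std(axis=0) == 0):
        bad = [names[i] for i in np.flatnonzero(X.std(axis=0) == 0)]
        raise ValueError(f"constant columns in design: {bad}")
    prep = coxph.prepare(times, events)
    if prep.n_events < 1:
        raise ValueError("Cox model requires at least one event")
    Xs = X[prep.order]
    res = coxph.newton_fit(prep, Xs, ties=ties, tol=tol, max_iter=max_iter,
                           beta0=initial_beta,
                           compute_null=initial_beta is None)
    if res.flag == "monotone_likelihood":
        warnings.warn(
            "monotone partial likelihood (perfect separation); "
            "coefficients are not identified", stacklevel=2)
    bt, bh = coxph.breslow_cumhaz(prep, Xs, res.beta)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = res.beta / res.se
    p = 2 * stats.norm.sf(np.abs(z))
    return CoxFit(
        names=tuple(names), coef=res.beta, se=res.se, cov=res.cov, z=z, p=p,
        loglik_null=res.loglik_null, loglik_fit=res.loglik,
        baseline_times=bt, baseline_cumhaz=bh, ties_method=ties,
        n=prep.n, n_events=prep.n_events, converged=res.converged,
        flag=res.flag,
    )


def predict_event_prob(fit: CoxFit, covariate_row, horizon: float):
    """Probability of an event by ``horizon`` months for given covariates.

    Uses the Breslow baseline: ``1 - exp(-H0(horizon) * exp(x @ beta))``.
    A horizon beyond the last observed event time uses the last step of H0
    and emits a warning.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    bt, bh = fit.baseline_times, fit.baseline_cumhaz
    if bt.size and horizon > bt[-1]:
        warnings.warn(
            f"horizon {horizon} is beyond the last event time {bt[-1]:.3g}; "
            "using the last baseline-hazard step", stacklevel=2)
    idx = np.searchsorted(bt, horizon, side="right") - 1
    H0 = 0.0 if idx < 0 else float(bh[idx])
    lp = fit.linear_predictor(covariate_row)
    prob = 1.0 - np.exp(-H0 * np.exp(lp))
    return float(prob[0]) if prob.size == 1 and np.ndim(covariate_row) == 1 else prob


def harrell_c(risk_scores, times, events) -> float:
    """Harrell's concordance index for right-censored data.

    A pair (i, j) is usable when subject i has an event and a strictly
    shorter time than subject j's observed time.  Higher risk must
    accompany shorter survival; tied risks count one half.
    """
    risk = np.asarray(risk_scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if not (risk.shape == times.shape == events.shape):
        raise ValueError("risk_scores, times and events must share a shape")
    usable = (events[:, None] == 1) & (times[:, None] < times[None, :])
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable (comparable) pairs")
    conc = usable & (risk[:, None] > risk[None, :])
    tied = usable & (risk[:, None] == risk[None, :])
    return float((conc.sum() + 0.5 * tied.sum()) / n_usable)
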