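"""Minimum-p-value optimal-cutoff search for dichotomising a biomarker
against a censored outcome.

For each candidate cutoff c, a univariate Cox model is fitted on the strict
indicator (biomarker > c) and the Wald p-value of its hazard ratio is
recorded; the selected cutoff minimises that p-value (ties broken toward
the smallest cutoff).  The method is deliberately anti-conservative — the
selected p-value is *not* multiplicity-corrected — because the downstream
bootstrap shrinkage step corrects the effect estimate instead.  A log-rank
(score-test) scan statistic is available for cross-checking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import coxph

__all__ = ["GridPolicy", "CutpointResult", "minp_cutpoint", "dichotomize"]


@dataclass(frozen=True)
class GridPolicy:
    """Candidate-grid rules for the cutoff scan.

    Candidates are the unique observed values between the configured
    quantiles, thinned to at most ``max_candidates`` evenly spaced unique
    values, and restricted so each side keeps at least
    ``min_group_fraction`` of the subjects and at least one event.
    """

    lower_quantile: float = 0.10
    upper_quantile: float = 0.90
    max_candidates: int = 100
    min_group_fraction: float = 0.02
    statistic: str = "cox_wald"   # or "logrank"

    def __post_init__(self):
        if not 0 <= self.lower_quantile < self.upper_quantile <= 1:
            raise ValueError("need 0 <= lower_quantile < upper_quantile <= 1")
        if self.max_candidates < 2:
            raise ValueError("max_candidates must be >= 2")
        if not 0 <= self.min_group_fraction < 0.5:
            raise ValueError("min_group_fraction must lie in [0, 0.5)")
        if self.statistic not in ("cox_wald", "logrank"):
            raise ValueError("statistic must be 'cox_wald' or 'logrank'")


@dataclass
class CutpointResult:
    candidate_cutoffs: np.ndarray
    hr_at_cutoff: np.ndarray
    hr_lower: np.ndarray
    hr_upper: np.ndarray
    wald_p_at_cutoff: np.ndarray
    selected_cutoff: float
    selected_hr: float
    selected_ci: tuple[float, float]
    selected_p: float
    grid_policy: GridPolicy
    grid_record: dict = field(default_factory=dict)
    n: int = 0
    n_events: int = 0
    selected_p_corrected: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutoff": self.candidate_cutoffs,
            "hr": self.hr_at_cutoff,
            "lower": self.hr_lower,
            "upper": self.hr_upper,
            "wald_p": self.wald_p_at_cutoff,
        })


def dichotomize(biomarker_values, cutoff: float) -> np.ndarray:
    """Strict indicator (biomarker > cutoff), as a 0/1 integer column."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return (np.asarray(biomarker_values, dtype=float) > cutoff).astype(int)


def _candidate_grid(values: np.ndarray, events: np.ndarray,
                    policy: GridPolicy):
    n = values.size
    lo, hi = np.quantile(values, [policy.lower_quantile,
                                  policy.upper_quantile])
    uniq = np.unique(values)
    cand = uniq[(uniq >= lo) & (uniq <= hi)]
    n_raw = cand.size
    if cand.size > policy.max_candidates:
        idx = np.unique(np.linspace(0, cand.size - 1,
                                    policy.max_candidates).round().astype(int))
        cand = cand[idx]
    if cand.size == 0:
        raise ValueError("no candidate cutoffs inside the quantile bounds")
    sv = np.sort(values)
    sve = np.sort(values[events == 1])
    n_above = n - np.searchsorted(sv, cand, side="right")
    n_below = n - n_above
    ev_above = sve.size - np.searchsorted(sve, cand, side="right")
    ev_below = sve.size - ev_above
    min_side = max(1, math.ceil(policy.min_group_fraction * n))
    keep = ((n_above >= min_side) & (n_below >= min_side)
            & (ev_above >= 1) & (ev_below >= 1))
    if not keep.any():
        raise ValueError(
            "no admissible candidate cutoff: every candidate violates the "
            f"group-size constraint (>= {min_side} subjects and >= 1 event "
            "on each side)")
    record = {
        "lower_quantile": policy.lower_quantile,
        "upper_quantile": policy.upper_quantile,
        "lower_bound": float(lo), "upper_bound": float(hi),
        "candidate_source": "unique observed values, quantile-thinned",
        "n_unique_in_bounds": int(n_raw),
        "n_candidates": int(keep.sum()),
        "min_subjects_per_side": int(min_side),
        "statistic": policy.statistic,
    }
    return cand[keep], record


def _altman_corrected_p(p_min: float, eps_low: float, eps_high: float) -> float:
    """Asymptotic multiplicity correction for a minimum p-value selected
    over cutoffs spanning the (eps_low, 1 - eps_high) quantile range."""
    z = stats.norm.isf(p_min / 2)
    if z <= 1.0:
        return 1.0
    phi = stats.norm.pdf(z)
    span = math.log((1 - eps_low) * (1 - eps_high) / (eps_low * eps_high))
    return float(min(1.0, phi * (z - 1 / z) * span + 4 * phi / z))


def minp_cutpoint(biomarker_values, times, events,
                  grid_policy: GridPolicy | None = None,
                  ties: str = "efron",
                  corrected_p: bool = False) -> CutpointResult:
    """Scan candidate cutoffs and select the one minimising the p-value.

    Requires at least two distinct biomarker values inside the grid bounds
    and at least one event on each side of every retained candidate.
    ``corrected_p=True`` additionally reports a multiplicity-corrected
    selected p-value (off by default: the pipeline corrects the effect
    estimate by shrinkage instead).
    """
    policy = grid_policy or GridPolicy()
    values = np.asarray(biomarker_values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("biomarker values must be finite")
    prep = coxph.prepare(times, events)
    cand, record = _candidate_grid(values, events, policy)
    beta, se, converged = coxph.scan_binary(prep, values, cand, ties=ties)
    if policy.statistic == "logrank":
        chi2 = coxph.score_test_binary(prep, values, cand, ties=ties)
        p = stats.chi2.sf(chi2, 1)
    else:
        with np.errstate(invalid="ignore"):
            p = 2 * stats.norm.sf(np.abs(beta / se))
    if not converged.all():
        n_bad = int((~converged).sum())
        warnings.warn(f"{n_bad} candidate cutoff(s) dropped "
                      "(non-converged fit)", stacklevel=2)
        cand, beta, se, p = (a[converged] for a in (cand, beta, se, p))
    if cand.size == 0:
        raise ValueError("no candidate cutoff produced a converged fit")
    z975 = stats.norm.ppf(0.975)
    hr = np.exp(beta)
    lower = np.exp(beta - z975 * se)
    upper = np.exp(beta + z975 * se)
    best = int(np.argmin(p))  # ascending candidates: first minimum = smallest
    p_cor = None
    if corrected_p:
        p_cor = _altman_corrected_p(float(p[best]), policy.lower_quantile,
                                    1.0 - policy.upper_quantile)
    return CutpointResult(
        candidate_cutoffs=cand, hr_at_cutoff=hr, hr_lower=lower,
        hr_upper=upper, wald_p_at_cutoff=p,
        selected_cutoff=float(cand[best]), selected_hr=float(hr[best]),
        selected_ci=(float(lower[best]), float(upper[best])),
        selected_p=float(p[best]), grid_policy=policy, grid_record=record,
        n=prep.n, n_events=prep.n_events, selected_p_corrected=p_cor,
    )
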