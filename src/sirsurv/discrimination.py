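"""Incremental-value evaluation of the inflammation biomarkers: Harrell's C
and the integrated discrimination improvement (IDI) comparing a clinical
Cox model with biomarker-augmented models.

The clinical ("basic") model carries age, AFP > 400 ng/mL, Child-Pugh class
dummies and staging dummies (BCLC by default, ITA.LI.CA selectable).  The
extended models add either the continuous block (log NLR + PLR per 100) or
the categorical CNP dummies (reference CNP = 0).

IDI at a fixed horizon t is the change, between models, of the
discrimination slope D = E[risk | event by t] - E[risk | event-free at t],
where predicted risks come from the Breslow baseline and the expectation
over the censored cohort uses inverse-probability-of-censoring weights
(IPCW) from a Kaplan-Meier fit of the censoring distribution; subjects
censored before the horizon contribute only through the weights.  With no
censoring all weights are 1 and the estimator reduces to the plain Pencina
difference.  Confidence intervals and p-values come from a subject-level
bootstrap that refits both models in every replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarkers import add_biomarkers, cnp_scores
from .io import CATEGORY_LEVELS
from .survival import CoxFit, cox_fit, harrell_c, kaplan_meier, predict_event_prob

__all__ = ["ModelSpec", "build_design", "fit_model", "censoring_weights",
           "discrimination_slope", "idi_from_risks", "idi",
           "DiscriminationResult", "model_comparison_report"]

STAGING_COLUMN = {"BCLC": "bclc", "ITA.LI.CA": "italica"}


@dataclass(frozen=True)
class ModelSpec:
    """Covariate specification of one survival model.

    ``biomarker_block``: "none" (the basic clinical model), "continuous"
    (log NLR + PLR/100) or "categorical" (CNP dummies vs CNP = 0).
    ``interactions`` may list pairs of design-column names whose product is
    added (off by default).
    """

    staging: str = "BCLC"
    biomarker_block: str = "none"
    covariates: tuple[str, ...] = ("age", "afp_gt400", "child_pugh", "staging")
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.staging not in STAGING_COLUMN:
            raise ValueError(f"staging must be one of {set(STAGING_COLUMN)}")
        if self.biomarker_block not in ("none", "continuous", "categorical"):
            raise ValueError("biomarker_block must be none, continuous or "
                             "categorical")


def _dummies(series: pd.Series, levels, prefix: str) -> dict:
    vals = series.to_numpy(dtype=object)
    cols = {}
    for level in levels[1:]:
        col = (vals == level).astype(float)
        if col.sum() == 0:
            warnings.warn(f"empty level {prefix}={level}; dummy dropped",
                          stacklevel=3)
            continue
        cols[f"{prefix}_{level}"] = col
    return cols


def build_design(cohort: pd.DataFrame, spec: ModelSpec,
                 cutoffs: dict | None = None) -> pd.DataFrame:
    """Encode a cohort into the design matrix of a model spec."""
    cols: dict = {}
    for cov in spec.covariates:
        if cov == "age":
            cols["age"] = cohort["age"].to_numpy(dtype=float)
        elif cov == "afp_gt400":
            cols["afp_gt400"] = cohort["afp_gt400"].to_numpy(dtype=float)
        elif cov == "child_pugh":
            cols.update(_dummies(cohort["child_pugh"],
                                 CATEGORY_LEVELS["child_pugh"], "child_pugh"))
        elif cov == "staging":
            col = STAGING_COLUMN[spec.staging]
            cols.update(_dummies(cohort[col], CATEGORY_LEVELS[col], col))
        else:
            cols[cov] = cohort[cov].to_numpy(dtype=float)
    if spec.biomarker_block != "none":
        work = cohort if "nlr" in cohort.columns else add_biomarkers(cohort)
        if spec.biomarker_block == "continuous":
            cols["log_nlr"] = np.log(work["nlr"].to_numpy(dtype=float))
            cols["plr_per_100"] = work["plr"].to_numpy(dtype=float) / 100.0
        else:
            if not cutoffs or "nlr" not in cutoffs or "plr" not in cutoffs:
                raise ValueError("categorical biomarker block requires NLR "
                                 "and PLR cutoffs")
            cnp = cnp_scores(work["nlr"], work["plr"],
                             cutoffs["nlr"], cutoffs["plr"])
            for level in (1, 2):
                col = (cnp == level).astype(float)
                if col.sum() == 0:
                    warnings.warn(f"empty level cnp={level}; dummy dropped",
                                  stacklevel=2)
                    continue
                cols[f"cnp_{level}"] = col
    X = pd.DataFrame(cols, index=cohort.index)
    for a, b in spec.interactions:
        X[f"{a}:{b}"] = X[a] * X[b]
    return X


def fit_model(cohort: pd.DataFrame, spec: ModelSpec,
              cutoffs: dict | None = None, ties: str = "efron") -> CoxFit:
    """Fit a spec's Cox model on a cohort (OS outcome)."""
    X = build_design(cohort, spec, cutoffs)
    fit = cox_fit(X, cohort["os_time"].to_numpy(dtype=float),
                  cohort["os_event"].to_numpy(dtype=float), ties=ties)
    fit.design_info = {"spec": spec, "columns": tuple(X.columns)}
    return fit


def censoring_weights(times, events, horizon: float,
                      cap: float = 20.0) -> np.ndarray:
    """IPCW weights at a fixed horizon from the censoring-distribution KM.

    Events by the horizon get 1/G(t-), horizon survivors 1/G(horizon), and
    subjects censored before the horizon 0.  Weights above ``cap`` are
    truncated with a warning.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    cens_curve = kaplan_meier(times, 1 - events)
    ct, cs = cens_curve.event_times, cens_curve.survival_prob

    def G_left(t):
        # left limit: steps strictly before t
        if ct.size == 0:       # nobody censored: G is identically 1
            return np.ones(np.shape(t))
        idx = np.searchsorted(ct, t, side="left") - 1
        return np.where(idx < 0, 1.0, cs[np.maximum(idx, 0)])

    w = np.zeros(times.size)
    ev_by_h = (times <= horizon) & (events == 1)
    at_h = times > horizon
    w[ev_by_h] = 1.0 / G_left(times[ev_by_h])
    w[at_h] = 1.0 / G_left(np.full(at_h.sum(), horizon + 1e-12))
    if np.any(w > cap):
        warnings.warn(f"{int((w > cap).sum())} censoring weight(s) above "
                      f"{cap} truncated", stacklevel=2)
        w = np.minimum(w, cap)
    return w


def discrimination_slope(risks, times, events, horizon: float,
                         weights=None, ipcw: bool = True) -> float:
    """Weighted mean risk among events by the horizon minus among
    event-free survivors."""
    risks = np.asarray(risks, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if weights is None:
        weights = censoring_weights(times, events, horizon) if ipcw \
            else np.ones(times.size)
    ev = (times <= horizon) & (events == 1)
    free = times > horizon
    if not ev.any():
        raise ValueError("no events by the horizon")
    if not free.any():
        raise ValueError("no event-free subjects at the horizon")
    mean_ev = np.average(risks[ev], weights=weights[ev])
    mean_free = np.average(risks[free], weights=weights[free])
    return float(mean_ev - mean_free)


def idi_from_risks(risk_base, risk_extended, times, events, horizon: float,
                   ipcw: bool = True) -> float:
    """IDI = discrimination slope of the extended minus the base risks."""
    w = censoring_weights(times, events, horizon) if ipcw else None
    d_ext = discrimination_slope(risk_extended, times, events, horizon,
                                 weights=w, ipcw=ipcw)
    d_base = discrimination_slope(risk_base, times, events, horizon,
                                  weights=w, ipcw=ipcw)
    return d_ext - d_base


@dataclass
class DiscriminationResult:
    c_index_base: float
    c_base_ci: tuple[float, float]
    c_index_extended: float
    c_ext_ci: tuple[float, float]
    idi: float
    idi_ci: tuple[float, float]
    idi_p: float
    horizon: float
    n_bootstrap: int
    n_failed_replicates: int
    censoring_weighting: str
    per_subject: pd.DataFrame = field(repr=False, default=None)
    seed: int | None = None

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "value": [self.c_index_base, self.c_index_extended, self.idi,
                      self.idi_p],
            "ci_lower": [self.c_base_ci[0], self.c_ext_ci[0],
                         self.idi_ci[0], np.nan],
            "ci_upper": [self.c_base_ci[1], self.c_ext_ci[1],
                         self.idi_ci[1], np.nan],
        }, index=["c_index_base", "c_index_extended", "idi", "idi_p"])


def idi(cohort: pd.DataFrame, base_spec: ModelSpec, extended_spec: ModelSpec,
        horizon: float = 36.0, n_bootstrap: int = 500,
        seed: int | None = None, cutoffs: dict | None = None,
        ipcw: bool = True, ties: str = "efron") -> DiscriminationResult:
    """IDI (and C-indices) of an extended model over a base model.

    Both models are refitted inside every bootstrap replicate so the
    interval reflects estimation as well as evaluation noise.
    """
    times = cohort["os_time"].to_numpy(dtype=float)
    events = cohort["os_event"].to_numpy(dtype=float)
    if not ((times <= horizon) & (events == 1)).any():
        raise ValueError("no events by the requested horizon")
    Xb = build_design(cohort, base_spec, cutoffs)
    Xe = build_design(cohort, extended_spec, cutoffs)

    def _risks(Xb_a, Xe_a, t, e, warm=(None, None)):
        fb = cox_fit(Xb_a, t, e, ties=ties, initial_beta=warm[0])
        fe = cox_fit(Xe_a, t, e, ties=ties, initial_beta=warm[1])
        if not (fb.converged and fe.converged):
            raise ValueError("model fit did not converge")
        rb = predict_event_prob(fb, Xb_a.to_numpy(dtype=float)
                                if isinstance(Xb_a, pd.DataFrame) else Xb_a,
                                horizon)
        re = predict_event_prob(fe, Xe_a.to_numpy(dtype=float)
                                if isinstance(Xe_a, pd.DataFrame) else Xe_a,
                                horizon)
        return np.asarray(rb), np.asarray(re)

    fb0 = cox_fit(Xb, times, events, ties=ties)
    fe0 = cox_fit(Xe, times, events, ties=ties)
    rb0 = np.asarray(predict_event_prob(fb0, Xb.to_numpy(dtype=float), horizon))
    re0 = np.asarray(predict_event_prob(fe0, Xe.to_numpy(dtype=float), horizon))
    idi0 = idi_from_risks(rb0, re0, times, events, horizon, ipcw=ipcw)
    c_base = harrell_c(rb0, times, events)
    c_ext = harrell_c(re0, times, events)

    rng = np.random.default_rng(seed)
    n = times.size
    Xb_np, Xe_np = Xb.to_numpy(dtype=float), Xe.to_numpy(dtype=float)
    idi_b = np.full(n_bootstrap, np.nan)
    cb_b = np.full(n_bootstrap, np.nan)
    ce_b = np.full(n_bootstrap, np.nan)
    n_failed = 0
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        try:
            t, e = times[idx], events[idx]
            if not ((t <= horizon) & (e == 1)).any():
                raise ValueError("no events by horizon in replicate")
            rb, re = _risks(Xb_np[idx], Xe_np[idx], t, e,
                            warm=(fb0.coef, fe0.coef))
            idi_b[b] = idi_from_risks(rb, re, t, e, horizon, ipcw=ipcw)
            cb_b[b] = harrell_c(rb, t, e)
            ce_b[b] = harrell_c(re, t, e)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    ok = ~np.isnan(idi_b)
    if not ok.any():
        raise RuntimeError("all bootstrap replicates failed")
    n_ok = int(ok.sum())
    draws = idi_b[ok]
    idi_ci = (float(np.percentile(draws, 2.5)),
              float(np.percentile(draws, 97.5)))
    if np.all(draws == draws[0]) and draws[0] == idi0:
        # degenerate bootstrap distribution (e.g. self-comparison)
        p = 1.0 if idi0 == 0 else min(1.0, 2 / (n_ok + 1))
    else:
        p = min(1.0, 2 * min(np.sum(draws <= 0) + 1,
                             np.sum(draws >= 0) + 1) / (n_ok + 1))
    per_subject = pd.DataFrame({"risk_base": rb0, "risk_extended": re0,
                                "os_time": times, "os_event": events},
                               index=cohort.index)
    return DiscriminationResult(
        c_index_base=c_base,
        c_base_ci=(float(np.percentile(cb_b[ok], 2.5)),
                   float(np.percentile(cb_b[ok], 97.5))),
        c_index_extended=c_ext,
        c_ext_ci=(float(np.percentile(ce_b[ok], 2.5)),
                  float(np.percentile(ce_b[ok], 97.5))),
        idi=idi0, idi_ci=idi_ci, idi_p=float(p), horizon=horizon,
        n_bootstrap=n_bootstrap, n_failed_replicates=n_failed,
        censoring_weighting="ipcw" if ipcw else "none",
        per_subject=per_subject, seed=seed,
    )


_ROW_LABELS = {
    "age": "Age", "afp_gt400": "AFP > 400 ng/ml",
    "child_pugh_B": "CHILD score B", "child_pugh_C": "CHILD score C",
    "bclc_A": "BCLC stage Early", "bclc_B": "BCLC stage Intermediate",
    "bclc_C": "BCLC stage Advanced", "bclc_D": "BCLC stage Terminal",
    "italica_A": "ITA.LI.CA stage A", "italica_B": "ITA.LI.CA stage B",
    "italica_C": "ITA.LI.CA stage C",
    "log_nlr": "Log (NLR)", "plr_per_100": "PLR (per 100)",
    "cnp_1": "CNP 1", "cnp_2": "CNP 2",
}

_REF_ROWS = {
    "child_pugh": "CHILD score A (Ref.)",
    "bclc": "BCLC stage Very Early (ref.)",
    "italica": "ITA.LI.CA stage 0 (ref.)",
    "cnp": "CNP 0",
}


@dataclass
class ComparisonReport:
    table: pd.DataFrame          # long/numeric: model, term, hr, lo, hi, p
    discrimination: pd.DataFrame  # per model: c-index, CI, IDI, IDI CI, p
    horizon: float
    staging: str
    cutoffs: dict

    def wide(self) -> pd.DataFrame:
        """Formatted three-column layout (one column per model)."""
        def fmt(r):
            if r["reference"]:
                return "1"
            return (f"{r['hr']:.2f} ({r['lo']:.2f}-{r['hi']:.2f}), "
                    f"p={r['p']:.3g}")
        t = self.table.copy()
        t["cell"] = t.apply(fmt, axis=1)
        wide = t.pivot(index="term", columns="model", values="cell")
        order = t.drop_duplicates("term")["term"]
        return wide.loc[order]

    def to_json_dict(self) -> dict:
        return {
            "horizon_months": self.horizon,
            "staging": self.staging,
            "cutoffs": self.cutoffs,
            "coefficients": self.table.to_dict(orient="records"),
            "discrimination": self.discrimination.reset_index()
                                  .to_dict(orient="records"),
        }


def model_comparison_report(cohort: pd.DataFrame, cutoffs: dict,
                            horizon: float = 36.0, staging: str = "BCLC",
                            n_bootstrap: int = 500, seed: int | None = None,
                            ipcw: bool = True) -> ComparisonReport:
    """Three-model comparison: clinical, clinical + continuous biomarkers,
    clinical + CNP, with per-covariate HRs, C-index and IDI vs clinical."""
    specs = {
        "Clinical": ModelSpec(staging=staging, biomarker_block="none"),
        "Clinical + continuous biomarkers":
            ModelSpec(staging=staging, biomarker_block="continuous"),
        "Clinical + categorical biomarkers":
            ModelSpec(staging=staging, biomarker_block="categorical"),
    }
    rows = []
    disc_rows = {}
    base_spec = specs["Clinical"]
    for model_name, spec in specs.items():
        fit = fit_model(cohort, spec, cutoffs)
        lo, hi = fit.confidence_intervals()
        seen_groups = set()
        for i, name in enumerate(fit.names):
            group = name.rsplit("_", 1)[0] if "_" in name else None
            if group in _REF_ROWS and group not in seen_groups:
                rows.append({"model": model_name, "term": _REF_ROWS[group],
                             "hr": 1.0, "lo": np.nan, "hi": np.nan,
                             "p": np.nan, "reference": True})
                seen_groups.add(group)
            rows.append({"model": model_name,
                         "term": _ROW_LABELS.get(name, name),
                         "hr": float(np.exp(fit.coef[i])), "lo": float(lo[i]),
                         "hi": float(hi[i]), "p": float(fit.p[i]),
                         "reference": False})
    # discrimination: extended models vs clinical
    for model_name, spec in specs.items():
        if spec.biomarker_block == "none":
            continue
        res = idi(cohort, base_spec, spec, horizon=horizon,
                  n_bootstrap=n_bootstrap, seed=seed, cutoffs=cutoffs,
                  ipcw=ipcw)
        disc_rows.setdefault("Clinical", {
            "c_index": res.c_index_base, "c_lower": res.c_base_ci[0],
            "c_upper": res.c_base_ci[1], "idi": np.nan,
            "idi_lower": np.nan, "idi_upper": np.nan, "idi_p": np.nan,
        })
        disc_rows[model_name] = {
            "c_index": res.c_index_extended, "c_lower": res.c_ext_ci[0],
            "c_upper": res.c_ext_ci[1], "idi": res.idi,
            "idi_lower": res.idi_ci[0], "idi_upper": res.idi_ci[1],
            "idi_p": res.idi_p,
        }
    table = pd.DataFrame(rows)
    disc = pd.DataFrame(disc_rows).T
    disc.index.name = "model"
    return ComparisonReport(table=table, discrimination=disc,
                            horizon=horizon, staging=staging, cutoffs=dict(cutoffs))
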