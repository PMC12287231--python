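"""Fractional-polynomial (FP) assessment of a biomarker's functional form
in the Cox model.

The candidate powers are the canonical set {-2, -1, -0.5, 0, 0.5, 1, 2, 3}
with 0 meaning log.  FP1 uses one power; FP2 uses a pair (p, q) with the
repeated-power rule x^p and x^p*log(x) when p == q.  The biomarker is
pre-scaled by its geometric mean for numerical stability (the power set
selected is invariant to positive rescaling).

Form selection uses the closed (RA2) testing procedure: best-FP2 against
the null model (4 df), against linear (3 df) and against best-FP1 (2 df),
each by a chi-square deviance difference at level alpha.  The search can
be adjusted for clinical covariates (on by default in the pipeline, which
mirrors a multivariable-FP analysis for a single continuous predictor).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import coxph
from .survival import CoxFit, cox_fit

__all__ = ["FP_POWERS", "FPForm", "FPResult", "fp_basis", "transform",
           "fp_select"]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass(frozen=True)
class FPForm:
    """A selected functional form.

    kind: one of "null", "linear", "fp1", "fp2"; ``powers`` holds the FP
    powers (empty for null/linear); ``scale`` is the pre-scaling constant
    (geometric mean) the basis divides by.
    """

    kind: str
    powers: tuple[float, ...] = ()
    scale: float = 1.0

    def label(self) -> str:
        if self.kind == "fp1":
            return f"fp1({self.powers[0]:g})"
        if self.kind == "fp2":
            return f"fp2({self.powers[0]:g},{self.powers[1]:g})"
        return self.kind


def _power_col(z: np.ndarray, p: float) -> np.ndarray:
    return np.log(z) if p == 0 else z ** p


def fp_basis(x, powers, scale: float = 1.0) -> np.ndarray:
    """FP basis columns for given powers (repeated-power rule for pairs)."""
    z = np.asarray(x, dtype=float) / scale
    if np.any(z <= 0):
        raise ValueError("fractional polynomials require strictly positive "
                         "values; shift the biomarker before the search")
    powers = tuple(powers)
    if len(powers) == 1:
        return _power_col(z, powers[0])[:, None]
    p, q = powers
    first = _power_col(z, p)
    if p == q:
        return np.column_stack([first, first * np.log(z)])
    return np.column_stack([first, _power_col(z, q)])


def transform(biomarker_values, form: FPForm) -> np.ndarray:
    """Transformed covariate column(s) for a selected form.

    Returns an (n, 0) array for the null form and the identity column for
    linear.
    """
    x = np.asarray(biomarker_values, dtype=float)
    if form.kind == "null":
        return np.empty((x.size, 0))
    if form.kind == "linear":
        return (x / form.scale)[:, None]
    return fp_basis(x, form.powers, form.scale)


@dataclass
class FPResult:
    candidate_powers: tuple[float, ...]
    dev_null: float
    dev_linear: float
    fp1_deviances: dict
    fp2_deviances: dict
    best_fp1_power: float
    best_fp2_pair: tuple[float, float]
    closed_test_pvalues: dict
    selected_form: FPForm
    alpha: float
    scale: float
    adjusted: bool
    selected_fit: CoxFit | None
    n_dropped_candidates: int

    def deviance_table(self) -> pd.DataFrame:
        rows = [("null", "", self.dev_null), ("linear", "1", self.dev_linear)]
        rows += [(f"fp1({p:g})", f"{p:g}", dv)
                 for p, dv in self.fp1_deviances.items()]
        rows += [(f"fp2({p:g},{q:g})", f"{p:g},{q:g}", dv)
                 for (p, q), dv in self.fp2_deviances.items()]
        return pd.DataFrame(rows, columns=["model", "powers", "deviance"])

    def effect_curve(self, grid=None, n_points: int = 100) -> pd.DataFrame:
        """Biomarker part of the linear predictor over a grid, centred at
        the geometric-mean point (for smooth effect-curve export)."""
        if self.selected_fit is None or self.selected_form.kind == "null":
            grid = np.asarray(grid if grid is not None else
                              np.linspace(self.scale / 2, self.scale * 2,
                                          n_points), dtype=float)
            return pd.DataFrame({"biomarker": grid,
                                 "log_hr": np.zeros(grid.size)})
        if grid is None:
            grid = np.geomspace(self.scale / 4, self.scale * 4, n_points)
        grid = np.asarray(grid, dtype=float)
        B = transform(grid, self.selected_form)
        B0 = transform(np.array([self.scale]), self.selected_form)
        k = B.shape[1]
        coef = self.selected_fit.coef[:k]
        lp = (B - B0) @ coef
        return pd.DataFrame({"biomarker": grid, "log_hr": lp})


def fp_select(biomarker_values, times, events, alpha: float = 0.05,
              adjust=None, ties: str = "efron") -> FPResult:
    """Select the functional form of a biomarker's effect on survival.

    Parameters
    ----------
    adjust : optional (n, m) array/DataFrame of clinical covariates every
        candidate model is adjusted for.
    alpha : level of the closed deviance tests.

    Returns the full deviance table, the closed-test p-values and the
    selected form (one of null, linear, fp1(p), fp2(p, q)).
    """
    x = np.asarray(biomarker_values, dtype=float)
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("biomarker must be strictly positive and finite; "
                         "pre-shift non-positive values before the search")
    prep = coxph.prepare(times, events)
    if prep.n_events < 10:
        warnings.warn(f"only {prep.n_events} events; fractional-polynomial "
                      "selection is unreliable below ~10", stacklevel=2)
    scale = float(np.exp(np.mean(np.log(x))))
    z = x / scale
    if adjust is None:
        A = np.empty((x.size, 0))
        adj_names: tuple[str, ...] = ()
    elif isinstance(adjust, pd.DataFrame):
        A = adjust.to_numpy(dtype=float)
        adj_names = tuple(map(str, adjust.columns))
    else:
        A = np.asarray(adjust, dtype=float)
        if A.ndim == 1:
            A = A[:, None]
        adj_names = tuple(f"adj{i}" for i in range(A.shape[1]))

    def _dev(B) -> float:
        design = np.column_stack([B, A]) if B.size else A
        if design.shape[1] == 0:
            ll, _, _ = coxph.loglik_grad_hess(prep, np.zeros((x.size, 1))[prep.order],
                                              np.zeros(1), ties)
            return -2.0 * ll
        res = coxph.newton_fit(prep, design[prep.order], ties=ties)
        if not res.converged:
            raise coxph.SingularDesignError("candidate fit did not converge")
        return -2.0 * res.loglik

    dev_null = _dev(np.empty((x.size, 0)))
    dev_linear = _dev(z[:, None])
    dropped = 0
    fp1_dev: dict = {}
    for p in FP_POWERS:
        try:
            fp1_dev[p] = _dev(fp_basis(x, (p,), scale))
        except (coxph.SingularDesignError, np.linalg.LinAlgError):
            warnings.warn(f"FP1 power {p:g} dropped (fit failed)", stacklevel=2)
            dropped += 1
    fp2_dev: dict = {}
    for p, q in itertools.combinations_with_replacement(FP_POWERS, 2):
        try:
            fp2_dev[(p, q)] = _dev(fp_basis(x, (p, q), scale))
        except (coxph.SingularDesignError, np.linalg.LinAlgError):
            warnings.warn(f"FP2 pair ({p:g},{q:g}) dropped (fit failed)",
                          stacklevel=2)
            dropped += 1
    if not fp1_dev or not fp2_dev:
        raise RuntimeError("all fractional-polynomial candidates failed")
    best_p1 = min(fp1_dev, key=fp1_dev.get)
    best_p2 = min(fp2_dev, key=fp2_dev.get)
    dev_fp1, dev_fp2 = fp1_dev[best_p1], fp2_dev[best_p2]

    pvals = {
        "fp2_vs_null": float(stats.chi2.sf(max(dev_null - dev_fp2, 0.0), 4)),
        "fp2_vs_linear": float(stats.chi2.sf(max(dev_linear - dev_fp2, 0.0), 3)),
        "fp2_vs_fp1": float(stats.chi2.sf(max(dev_fp1 - dev_fp2, 0.0), 2)),
    }
    if pvals["fp2_vs_null"] > alpha:
        form = FPForm("null", (), scale)
    elif pvals["fp2_vs_linear"] > alpha:
        form = FPForm("linear", (), scale)
    elif pvals["fp2_vs_fp1"] > alpha:
        form = FPForm("fp1", (best_p1,), scale)
    else:
        form = FPForm("fp2", best_p2, scale)

    selected_fit = None
    if form.kind != "null":
        B = transform(x, form)
        names = tuple(f"biomarker_{i}" for i in range(B.shape[1])) + adj_names
        design = np.column_stack([B, A]) if A.size else B
        selected_fit = cox_fit(design, times, events, ties=ties, names=names)
    return FPResult(
        candidate_powers=FP_POWERS, dev_null=dev_null, dev_linear=dev_linear,
        fp1_deviances=fp1_dev, fp2_deviances=fp2_dev,
        best_fp1_power=best_p1, best_fp2_pair=best_p2,
        closed_test_pvalues=pvals, selected_form=form, alpha=alpha,
        scale=scale, adjusted=A.shape[1] > 0, selected_fit=selected_fit,
        n_dropped_candidates=dropped,
    )
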