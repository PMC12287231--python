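"""End-to-end orchestration of the biomarker prognostic analysis.

``run_os_analysis`` executes, in order: biomarker computation ->
fractional-polynomial functional-form assessment -> continuous-effect Cox
-> minimum-p cutoff per biomarker -> dichotomised Cox with bootstrap
shrinkage (unadjusted and clinically adjusted) -> CNP construction with
three-group Kaplan-Meier / log-rank -> model-comparison report (C-index,
IDI).  ``run_rfs_analysis`` reuses the OS cutoffs on the curative-treatment
subset with the early-recurrence exclusion rule.  All tabular outputs are
TSV, the manifest is JSON, and a fixed seed makes the whole run
reproducible byte for byte (the manifest's ``created`` timestamp aside).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import add_biomarkers, cnp_scores
from .cutpoints import GridPolicy, dichotomize, minp_cutpoint
from .discrimination import ModelSpec, build_design, model_comparison_report
from .functional_form import fp_select
from .io import CATEGORY_LEVELS, load_config_file, read_cohort, write_cohort
from .shrinkage import bootstrap_shrinkage, shrinkage_report
from .simulate import SimulationConfig, simulate_cohort
from .survival import kaplan_meier, logrank_test

__all__ = ["RFSRules", "AnalysisConfig", "RunManifest", "ValidationReport",
           "validate_cohort", "validate_cohort_file", "run_os_analysis",
           "run_rfs_analysis"]

logger = logging.getLogger("sirsurv")

REQUIRED_COLUMNS = ("subject_id", "age", "afp_gt400", "child_pugh", "bclc",
                    "neutrophils", "lymphocytes", "platelets",
                    "os_time", "os_event")

CURATIVE_TREATMENTS = ("LT", "LR", "ABL")


@dataclass(frozen=True)
class RFSRules:
    """Recurrence-analysis rules: curative treatments and the exclusion of
    recurrences within the initial window (months).  ``landmark_censor``
    switches the exclusion rule to a landmark analysis (drop everyone with
    follow-up shorter than the window, restart the clock there)."""

    curative: tuple[str, ...] = CURATIVE_TREATMENTS
    exclusion_window: float = 3.0
    landmark_censor: bool = False

    def __post_init__(self):
        if self.exclusion_window < 0:
            raise ValueError("exclusion window must be >= 0")


@dataclass
class AnalysisConfig:
    """Configuration of a pipeline run (see docs/methods.md for defaults)."""

    seed: int
    input: object = None                 # path to cohort CSV or SimulationConfig
    output_dir: str | Path = "sirsurv_out"
    outcome: str = "OS"
    grid_policy: GridPolicy = field(default_factory=GridPolicy)
    n_bootstrap_shrinkage: int = 1000
    n_bootstrap_idi: int = 500
    horizon: float = 36.0
    staging: str = "BCLC"
    fp_adjusted: bool = True
    alpha: float = 0.05
    rfs_rules: RFSRules = field(default_factory=RFSRules)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        data = load_config_file(path)
        if isinstance(data.get("input"), dict):
            data["input"] = SimulationConfig(**data["input"])
        if isinstance(data.get("grid_policy"), dict):
            data["grid_policy"] = GridPolicy(**data["grid_policy"])
        if isinstance(data.get("rfs_rules"), dict):
            rules = dict(data["rfs_rules"])
            if "curative" in rules:
                rules["curative"] = tuple(rules["curative"])
            data["rfs_rules"] = RFSRules(**rules)
        return cls(**data)


@dataclass
class RunManifest:
    """Record-count bookkeeping and configuration snapshot of one run."""

    config: dict
    package_version: str
    seed: int
    counts: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    created: str = ""

    def add_stage(self, name: str, **info):
        self.stages.append({"stage": name, **info})
        logger.info("stage %s: %s", name, info)

    def stage_log(self) -> str:
        """Plain-text one-line-per-stage log (no timestamps, so seeded
        runs stay byte-identical)."""
        return "".join(f"{s['stage']}: "
                       + ", ".join(f"{k}={v}" for k, v in s.items()
                                   if k != "stage") + "\n"
                       for s in self.stages)

    def to_json(self) -> str:
        payload = asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True, default=str)

    def write(self, path):
        Path(path).write_text(self.to_json() + "\n")


@dataclass
class ValidationReport:
    n_rows: int
    violations: pd.DataFrame

    @property
    def ok(self) -> bool:
        return self.violations.empty


def _check_rows(cohort: pd.DataFrame) -> list[dict]:
    issues = []

    def flag(mask, rule, column):
        for i in np.flatnonzero(np.asarray(mask)):
            sid = cohort["subject_id"].iloc[i] if "subject_id" in cohort \
                else str(i)
            issues.append({"row": int(i), "subject_id": sid, "rule": rule,
                           "column": column,
                           "value": repr(cohort[column].iloc[i])})

    for col in REQUIRED_COLUMNS:
        if col not in cohort.columns:
            issues.append({"row": -1, "subject_id": "", "column": col,
                           "rule": "missing_required_column", "value": ""})
    if issues:
        return issues
    num = {c: pd.to_numeric(cohort[c], errors="coerce")
           for c in ("age", "afp_gt400", "neutrophils", "lymphocytes",
                     "platelets", "os_time", "os_event")}
    for c, v in num.items():
        flag(v.isna(), "non_numeric_or_missing", c)
    flag(num["lymphocytes"] <= 0, "lymphocytes_not_positive", "lymphocytes")
    for c in ("neutrophils", "platelets"):
        flag(num[c] <= 0, "count_not_positive", c)
    flag(num["os_time"] < 0, "negative_time", "os_time")
    flag(~num["os_event"].isin([0, 1]) & num["os_event"].notna(),
         "event_not_binary", "os_event")
    flag(~num["afp_gt400"].isin([0, 1]) & num["afp_gt400"].notna(),
         "indicator_not_binary", "afp_gt400")
    for col in ("child_pugh", "bclc", "italica", "treatment"):
        if col not in cohort.columns:
            continue
        vals = cohort[col].astype(object)
        present = vals.notna() & (vals != "")
        optional = col in ("italica", "treatment")
        bad = present & ~vals.isin(CATEGORY_LEVELS[col])
        if not optional:
            bad = bad | ~present
        flag(bad, "out_of_vocabulary", col)
    if "rfs_time" in cohort.columns:
        rt = pd.to_numeric(cohort["rfs_time"], errors="coerce")
        flag(rt.notna() & (rt < 0), "negative_time", "rfs_time")
    return issues


def validate_cohort(cohort: pd.DataFrame) -> ValidationReport:
    """Schema and plausibility checks; never coerces silently."""
    issues = _check_rows(cohort)
    cols = ["row", "subject_id", "column", "rule", "value"]
    return ValidationReport(n_rows=len(cohort),
                            violations=pd.DataFrame(issues, columns=cols))


def validate_cohort_file(path) -> ValidationReport:
    """Validate a cohort CSV on disk (row-level error list)."""
    return validate_cohort(read_cohort(path))


def _load_or_simulate(config: AnalysisConfig):
    if isinstance(config.input, SimulationConfig):
        return simulate_cohort(config.input), True
    if isinstance(config.input, (str, Path)):
        return read_cohort(config.input), False
    raise ValueError("config.input must be a cohort CSV path or a "
                     "SimulationConfig")


def _clinical_design(cohort: pd.DataFrame, staging: str) -> pd.DataFrame:
    return build_design(cohort, ModelSpec(staging=staging,
                                          biomarker_block="none"))


def _manifest_for(config: AnalysisConfig) -> RunManifest:
    cfg = asdict(config)
    if isinstance(config.input, SimulationConfig):
        cfg["input"] = config.input.to_dict()
    else:
        cfg["input"] = str(config.input)
    return RunManifest(config=cfg, package_version=__version__,
                       seed=config.seed,
                       created=datetime.now(timezone.utc).isoformat())


def _write_tsv(df: pd.DataFrame, path, index=False):
    df.to_csv(path, sep="\t", index=index, na_rep="NA",
              float_format="%.10g")


def run_os_analysis(config: AnalysisConfig) -> dict:
    """Full overall-survival analysis; returns the result bundle and writes
    all tables, curve data and the manifest to ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_for(config)
    bundle: dict = {"manifest": manifest}
    try:
        cohort, simulated = _load_or_simulate(config)
        n_in = len(cohort)
        report = validate_cohort(cohort)
        bad_rows = sorted(set(report.violations["row"]) - {-1})
        if -1 in set(report.violations["row"]):
            raise ValueError("cohort is missing required columns: "
                             + ", ".join(report.violations["column"]))
        if bad_rows:
            cohort = cohort.drop(cohort.index[bad_rows]).reset_index(drop=True)
        manifest.counts["subjects_in"] = n_in
        manifest.counts["excluded_invalid"] = len(bad_rows)
        manifest.counts["analyzed"] = len(cohort)
        manifest.add_stage("load", subjects_in=n_in,
                           excluded_invalid=len(bad_rows),
                           analyzed=len(cohort), simulated=simulated)
        if simulated:
            write_cohort(cohort, out / "cohort.csv")

        cohort = add_biomarkers(cohort)
        times = cohort["os_time"].to_numpy(dtype=float)
        events = cohort["os_event"].to_numpy(dtype=float)
        manifest.add_stage("biomarkers", n=len(cohort))

        clin = _clinical_design(cohort, config.staging)
        adjust = clin if config.fp_adjusted else None
        fp_results = {}
        scans = {}
        shrinkages = {}
        cutoffs = {}
        rng = np.random.default_rng(config.seed)
        for name in ("nlr", "plr"):
            values = cohort[name].to_numpy(dtype=float)
            fp = fp_select(values, times, events, alpha=config.alpha,
                           adjust=adjust)
            fp_results[name] = fp
            _write_tsv(fp.deviance_table(), out / f"fp_deviances_{name}.tsv")
            _write_tsv(fp.effect_curve(), out / f"effect_curve_{name}.tsv")
            scan = minp_cutpoint(values, times, events, config.grid_policy)
            scans[name] = scan
            cutoffs[name] = scan.selected_cutoff
            _write_tsv(scan.to_frame(), out / f"cutpoint_scan_{name}.tsv")
            seed_u = int(rng.integers(0, 2**31 - 1))
            seed_a = int(rng.integers(0, 2**31 - 1))
            unadj = bootstrap_shrinkage(
                values, times, events, adjust=None,
                grid_policy=config.grid_policy,
                n_bootstrap=config.n_bootstrap_shrinkage, seed=seed_u,
                biomarker=name)
            adj = bootstrap_shrinkage(
                values, times, events, adjust=clin,
                grid_policy=config.grid_policy,
                n_bootstrap=config.n_bootstrap_shrinkage, seed=seed_a,
                biomarker=name)
            shrinkages[name] = {"unadjusted": unadj, "adjusted": adj}
            _write_tsv(shrinkage_report(unadj, adj),
                       out / f"shrinkage_{name}.tsv")
            manifest.add_stage(
                f"cutpoint_{name}", cutoff=scan.selected_cutoff,
                selected_p=scan.selected_p,
                failed_replicates_unadjusted=unadj.n_failed_replicates,
                failed_replicates_adjusted=adj.n_failed_replicates)

        cnp = cnp_scores(cohort["nlr"], cohort["plr"],
                         cutoffs["nlr"], cutoffs["plr"])
        cohort["cnp"] = cnp
        group_counts = {int(k): int(v)
                        for k, v in pd.Series(cnp).value_counts().items()}
        manifest.counts["cnp_groups"] = group_counts
        km_frames = []
        for level in sorted(group_counts):
            mask = cnp == level
            curve = kaplan_meier(times[mask], events[mask])
            frame = curve.to_frame()
            frame.insert(0, "cnp", level)
            km_frames.append(frame)
            _write_tsv(frame, out / f"km_cnp_{level}.tsv")
        lr = logrank_test(times, events, cnp)
        manifest.add_stage("cnp", groups=group_counts,
                           logrank_chi2=lr.statistic, logrank_p=lr.p_value)
        bundle["cnp_logrank"] = lr
        bundle["cnp_km"] = pd.concat(km_frames, ignore_index=True)

        comparison = model_comparison_report(
            cohort, cutoffs, horizon=config.horizon, staging=config.staging,
            n_bootstrap=config.n_bootstrap_idi,
            seed=int(rng.integers(0, 2**31 - 1)))
        _write_tsv(comparison.table, out / "model_comparison.tsv")
        _write_tsv(comparison.discrimination, out / "model_discrimination.tsv",
                   index=True)
        (out / "model_comparison.json").write_text(
            json.dumps(comparison.to_json_dict(), indent=2, sort_keys=True,
                       default=str) + "\n")
        manifest.add_stage("model_comparison", horizon=config.horizon)

        bundle.update(cohort=cohort, fp=fp_results, scans=scans,
                      shrinkage=shrinkages, cutoffs=cutoffs,
                      comparison=comparison)
        manifest.write(out / "manifest.json")
        (out / "run.log").write_text(manifest.stage_log())
        return bundle
    except Exception as exc:
        manifest.add_stage("aborted", error=str(exc))
        manifest.write(out / "manifest.json")
        (out / "run.log").write_text(manifest.stage_log())
        raise


def run_rfs_analysis(config: AnalysisConfig, cutoffs: dict) -> dict:
    """Recurrence-free-survival analysis using cutoffs frozen from the OS
    analysis (they are *not* re-selected here)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_for(config)
    rules = config.rfs_rules
    cohort, _ = _load_or_simulate(config)
    cohort = add_biomarkers(cohort)
    n_in = len(cohort)
    curative = cohort[cohort["treatment"].isin(rules.curative)].copy()
    curative = curative[pd.to_numeric(curative["rfs_time"],
                                      errors="coerce").notna()]
    n_curative = len(curative)
    rt = curative["rfs_time"].to_numpy(dtype=float)
    re = curative["rfs_event"].to_numpy(dtype=float)
    if n_curative == 0:
        manifest.add_stage("aborted", error="empty curative subset")
        manifest.write(out / "manifest_rfs.json")
        raise ValueError("empty curative-treatment subset")
    if rules.landmark_censor:
        keep = rt > rules.exclusion_window
        curative = curative[keep]
        rt = rt[keep] - rules.exclusion_window
        re = re[keep]
        excluded = int((~keep).sum())
    else:
        early = (re == 1) & (rt < rules.exclusion_window)
        curative = curative[~early]
        rt, re = rt[~early], re[~early]
        excluded = int(early.sum())
    manifest.counts.update(subjects_in=n_in, curative=n_curative,
                           excluded_early_recurrence=excluded,
                           analyzed=len(curative))
    manifest.add_stage("rfs_subset", curative=n_curative,
                       excluded_early=excluded, analyzed=len(curative))

    groupings = {
        "nlr": dichotomize(curative["nlr"], cutoffs["nlr"]),
        "plr": dichotomize(curative["plr"], cutoffs["plr"]),
        "cnp": cnp_scores(curative["nlr"], curative["plr"],
                          cutoffs["nlr"], cutoffs["plr"]),
    }
    logranks = {}
    median_rows = []
    for name, groups in groupings.items():
        frames = []
        for level in np.unique(groups):
            mask = groups == level
            curve = kaplan_meier(rt[mask], re[mask])
            frame = curve.to_frame()
            frame.insert(0, "group", level)
            frames.append(frame)
            median_rows.append({"grouping": name, "group": int(level),
                                "n": int(mask.sum()),
                                "median_rfs": curve.median_survival,
                                "median_lower": curve.median_ci[0],
                                "median_upper": curve.median_ci[1]})
        _write_tsv(pd.concat(frames, ignore_index=True),
                   out / f"rfs_km_{name}.tsv")
        if len(np.unique(groups)) >= 2:
            logranks[name] = logrank_test(rt, re, groups)
    for trt in rules.curative:
        mask = (curative["treatment"] == trt).to_numpy()
        if mask.sum() == 0:
            continue
        curve = kaplan_meier(rt[mask], re[mask])
        median_rows.append({"grouping": "treatment", "group": trt,
                            "n": int(mask.sum()),
                            "median_rfs": curve.median_survival,
                            "median_lower": curve.median_ci[0],
                            "median_upper": curve.median_ci[1]})
    medians = pd.DataFrame(median_rows)
    _write_tsv(medians, out / "rfs_medians.tsv")
    manifest.add_stage("rfs_analysis",
                       logrank_p={k: v.p_value for k, v in logranks.items()})
    manifest.write(out / "manifest_rfs.json")
    return {"manifest": manifest, "cohort": curative, "medians": medians,
            "logrank": logranks, "groupings": groupings}
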