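"""Cohort CSV and configuration-file I/O.

The cohort schema (one row per subject)::

    subject_id, age, afp_gt400, child_pugh, bclc, italica,
    neutrophils, lymphocytes, platelets,
    os_time, os_event, rfs_time, rfs_event, treatment

Counts are in 10^3 cells/mm^3; times in months; ``afp_gt400``/``os_event``/
``rfs_event`` are 0/1; ``child_pugh`` in {A,B,C}; ``bclc`` in {0,A,B,C,D};
``italica`` in {0,A,B,C} (optional alternate staging); ``treatment`` in
{LT,LR,ABL,IAT,SOR,BSC}.  Optional fields (rfs_*, treatment, italica) may be
empty.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["COHORT_COLUMNS", "CATEGORY_LEVELS", "write_cohort",
           "read_cohort", "load_config_file"]

COHORT_COLUMNS = [
    "subject_id", "age", "afp_gt400", "child_pugh", "bclc", "italica",
    "neutrophils", "lymphocytes", "platelets",
    "os_time", "os_event", "rfs_time", "rfs_event", "treatment",
]

CATEGORY_LEVELS = {
    "child_pugh": ("A", "B", "C"),
    "bclc": ("0", "A", "B", "C", "D"),
    "italica": ("0", "A", "B", "C"),
    "treatment": ("LT", "LR", "ABL", "IAT", "SOR", "BSC"),
}

_STRING_COLUMNS = ["subject_id", "child_pugh", "bclc", "italica", "treatment"]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV with the documented column order."""
    cols = [c for c in COHORT_COLUMNS if c in cohort.columns]
    cohort.to_csv(path, index=False, columns=cols, na_rep="")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV; categorical columns stay as strings."""
    df = pd.read_csv(path, dtype={c: "string" for c in _STRING_COLUMNS})
    for c in _STRING_COLUMNS:
        if c in df.columns:
            df[c] = df[c].astype(object)
    return df


def load_config_file(path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return data
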