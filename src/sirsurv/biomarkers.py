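"""NLR, PLR and the combined CNP score.

NLR = neutrophils / lymphocytes; PLR = platelets / lymphocytes, both exact
quotients of absolute counts (accepted in 10^3 cells/mm^3; the ratios are
unit-free).  The CNP score counts how many of the two biomarkers exceed
their cutoffs, with a *strict* inequality: a value equal to the cutoff
belongs to the lower group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["BiomarkerPanel", "compute_panel", "add_biomarkers",
           "compute_cnp", "cnp_scores"]


@dataclass(frozen=True)
class BiomarkerPanel:
    nlr: float
    plr: float


def compute_panel(record: Mapping) -> BiomarkerPanel:
    """Compute the NLR/PLR panel for one subject.

    ``record`` is any mapping (dict, pandas row) with ``neutrophils``,
    ``lymphocytes`` and ``platelets`` counts.
    """
    lym = float(record["lymphocytes"])
    if not np.isfinite(lym) or lym <= 0:
        sid = record.get("subject_id", "<unknown>") if hasattr(record, "get") \
            else "<unknown>"
        raise ValueError(
            f"subject {sid}: lymphocytes must be positive (got {lym!r})")
    return BiomarkerPanel(nlr=float(record["neutrophils"]) / lym,
                          plr=float(record["platelets"]) / lym)


def add_biomarkers(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the cohort with ``nlr`` and ``plr`` columns added."""
    lym = cohort["lymphocytes"].to_numpy(dtype=float)
    bad = ~np.isfinite(lym) | (lym <= 0)
    if bad.any():
        ids = cohort.loc[bad, "subject_id"].tolist() if "subject_id" in cohort \
            else list(np.flatnonzero(bad))
        raise ValueError(f"non-positive lymphocyte counts for subjects {ids[:10]}")
    out = cohort.copy()
    out["nlr"] = cohort["neutrophils"].to_numpy(dtype=float) / lym
    out["plr"] = cohort["platelets"].to_numpy(dtype=float) / lym
    return out


def cnp_scores(nlr, plr, c_nlr: float, c_plr: float) -> np.ndarray:
    """Vectorised CNP score: (NLR > c_NLR) + (PLR > c_PLR), in {0, 1, 2}."""
    if not (c_nlr > 0 and c_plr > 0):
        raise ValueError("cutoffs must be positive")
    nlr = np.asarray(nlr, dtype=float)
    plr = np.asarray(plr, dtype=float)
    return (nlr > c_nlr).astype(int) + (plr > c_plr).astype(int)


def compute_cnp(panel: BiomarkerPanel, c_nlr: float, c_plr: float) -> int:
    """CNP score for one subject's panel."""
    return int(cnp_scores(panel.nlr, panel.plr, c_nlr, c_plr))
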