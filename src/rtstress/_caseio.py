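"""Rebuild CaseRecord lists from a flat scored case table.

The inverse of :func:`rtstress.synth.case_table`, used by the CLI and
by report regeneration: downstream numbers recomputed from the saved
table must match the original run exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import score as score_mod
from .types import FEATURE_ORDER, CaseRecord, HRVFeatures, IrregularityResult

__all__ = ["cases_from_table"]

_FEATURE_KEYS = ("hr", "sdnn", "rmssd", "pnn50", "lf", "hf", "lf_hf", "tp")


def _features(row: pd.Series, phase: str) -> HRVFeatures | None:
    vals = {}
    for k in _FEATURE_KEYS:
        col = f"{phase}_{k}"
        if col not in row.index:
            return None
        v = row[col]
        vals[k] = None if (k == "lf_hf" and pd.isna(v)) else float(v)
    return HRVFeatures(**vals)


def cases_from_table(table: pd.DataFrame | str | Path) -> list[CaseRecord]:
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    cases: list[CaseRecord] = []
    for _, row in df.iterrows():
        before = _features(row, "before")
        during = _features(row, "during")
        assessment = None
        if before is not None and during is not None:
            assessment = score_mod.assess(before, during)
        irr = None
        if "phase_irr" in row.index and not pd.isna(row["phase_irr"]):
            irr = IrregularityResult(
                amplitude_irr=float(row.get("amplitude_irr", np.nan)),
                phase_irr=float(row["phase_irr"]),
            )
        cases.append(
            CaseRecord(
                patient_id=str(row["patient_id"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                day=int(row["day"]),
                before=before,
                during=during,
                assessment=assessment,
                irregularity=irr,
            )
        )
    return cases
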