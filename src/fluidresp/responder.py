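"""Fluid-responder classification from the post-challenge stroke-volume change.

A patient is a fluid responder when stroke volume rises by at least 10%
after the fluid bolus, measured from the second (post-PEEP-withdrawal)
baseline T3 to five minutes after fluid loading T4. The boundary value of
exactly +10% counts as a responder; patients missing either SV reading are
flagged unclassifiable rather than dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["percent_sv_change", "classify_record", "classify_cohort"]

RESPONDER_THRESHOLD_PERCENT = 10.0


def percent_sv_change(sv_before: float, sv_after: float) -> float:
    """Signed percent stroke-volume change, 100*(after - before)/before."""
    if sv_before <= 0:
        raise ValueError("sv_before must be positive")
    return 100.0 * (sv_after - sv_before) / sv_before


def classify_record(
    sv_before: float, sv_after: float, threshold: float = RESPONDER_THRESHOLD_PERCENT
) -> bool:
    """True iff the SV rise meets the responder threshold (>= threshold)."""
    return percent_sv_change(sv_before, sv_after) >= threshold


def classify_cohort(
    cohort: pd.DataFrame,
    threshold: float = RESPONDER_THRESHOLD_PERCENT,
    sv_before_col: str = "SV_T3",
    sv_after_col: str = "SV_T4",
) -> pd.DataFrame:
    """Set/overwrite the ``responder`` column of a cohort table.

    Rows with a missing SV at either time point get ``responder = NA`` and
    ``unclassifiable = True``; they are retained in the output.
    """
    for col in (sv_before_col, sv_after_col):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing column {col!r}")
    out = cohort.copy()
    before = out[sv_before_col].to_numpy(dtype=float)
    after = out[sv_after_col].to_numpy(dtype=float)
    ok = np.isfinite(before) & np.isfinite(after)
    if np.any(before[ok] <= 0):
        raise ValueError("stroke volume at the pre-loading time point must be positive")
    change = np.full(before.shape, np.nan)
    change[ok] = 100.0 * (after[ok] - before[ok]) / before[ok]
    out["sv_change_percent"] = change
    responder = pd.array([None] * len(out), dtype="boolean")
    responder[ok] = change[ok] >= threshold
    out["responder"] = responder
    out["unclassifiable"] = ~ok
    return out
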