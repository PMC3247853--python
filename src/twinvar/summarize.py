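"""Cohort-level summaries of per-antibody variance breakdowns."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import ProportionBreakdown

__all__ = ["cohort_summary", "round_half_away"]

_TOTAL = ("fam", "env", "cv", "iv", "exp")
_NONEXP = ("fam_ne", "env_ne", "cv_ne", "iv_ne")


def round_half_away(x: float) -> int:
    """Round with halves away from zero (matching hand-rounded tables)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def cohort_summary(
    breakdowns: list[ProportionBreakdown] | pd.DataFrame,
) -> pd.DataFrame:
    """Median and IQR of each variance-proportion component across antibodies.

    Returns a table with columns (component, median, q1, q3, n). Besides
    the five total-variance shares this reports ``stable`` (the per-antibody
    familial + individual-environment share, the longitudinally stable
    biological fraction) and the non-experimental re-expressions; antibodies
    whose variance is purely experimental are excluded from the latter only.
    """
    if isinstance(breakdowns, pd.DataFrame):
        df = breakdowns.copy()
    else:
        if not breakdowns:
            raise ValueError("no breakdowns to summarise")
        df = pd.DataFrame([b.as_dict() for b in breakdowns])
    if df.empty:
        raise ValueError("no breakdowns to summarise")
    df["stable"] = df["fam"] + df["env"]
    if {"fam_ne", "env_ne"} <= set(df.columns):
        df["stable_ne"] = df["fam_ne"] + df["env_ne"]
    rows = []
    for comp in (*_TOTAL, "stable", *_NONEXP, "stable_ne"):
        if comp not in df.columns:
            continue
        col = df[comp].astype(float).dropna()
        if col.empty:
            continue
        rows.append({
            "component": comp,
            "median": float(col.median()),
            "q1": float(col.quantile(0.25)),
            "q3": float(col.quantile(0.75)),
            "n": int(col.size),
        })
    return pd.DataFrame(rows)
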