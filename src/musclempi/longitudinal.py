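"""Rates of change, annualized relative rates, and severity-stratified comparisons.

A rate of change is the difference between two time points divided by the
elapsed time in years.  The relative rate annualizes the percent change
from baseline: ``[100 * (last - first) / first] / duration_years``.  Each
subject's own elapsed time is used, never a cohort-median interval.
Summaries throughout are median (IQR), the convention for these skewed
clinical distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult
from scipy import stats as sps


@dataclass
class RateRecord:
    subject_id: str
    variable: str
    interval: tuple[int, int]  # (visit_a, visit_b) indices
    rate: float  # units / year
    relative_rate: float | None  # % / year, None when baseline is 0


def rate_of_change(v1: float, v2: float, t1_years: float, t2_years: float) -> float:
    """(v2 - v1) / (t2 - t1); antisymmetric under swapping the two points."""
    dt = t2_years - t1_years
    if dt <= 0:
        raise ValueError(f"interval duration must be positive, got {dt} years")
    return (v2 - v1) / dt


def relative_rate(first: float, last: float, duration_years: float) -> float:
    """Annualized percent change from baseline."""
    if duration_years <= 0:
        raise ValueError("duration must be positive")
    if first == 0:
        raise ValueError("relative rate undefined for zero baseline")
    return 100.0 * (last - first) / first / duration_years


def _iqr_text(x) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} ({q1:.2f}-{q3:.2f})"


def rates_table(
    values: pd.DataFrame,
    variables,
    time_col: str = "visit_time_years",
    interval: str = "first_last",
) -> pd.DataFrame:
    """Per-subject rates for the given variable columns.

    ``values`` holds one row per subject-visit with columns ``subject_id``,
    ``visit_index``, the time column, and the variables.  ``interval`` is
    ``"first_last"`` (one rate per subject over the whole follow-up) or
    ``"consecutive"`` (one per adjacent visit pair).
    """
    rows = []
    for sid, grp in values.groupby("subject_id", sort=True):
        grp = grp.sort_values("visit_index")
        if len(grp) < 2:
            continue
        if interval == "first_last":
            pairs = [(grp.iloc[0], grp.iloc[-1])]
        elif interval == "consecutive":
            pairs = [(grp.iloc[i], grp.iloc[i + 1]) for i in range(len(grp) - 1)]
        else:
            raise ValueError(f"unknown interval mode {interval!r}")
        for a, b in pairs:
            for var in variables:
                r = rate_of_change(a[var], b[var], a[time_col], b[time_col])
                rel = (
                    relative_rate(a[var], b[var], b[time_col] - a[time_col])
                    if a[var] != 0
                    else np.nan
                )
                rows.append(
                    {
                        "subject_id": sid,
                        "variable": var,
                        "visit_a": int(a["visit_index"]),
                        "visit_b": int(b["visit_index"]),
                        "duration_years": b[time_col] - a[time_col],
                        "rate": r,
                        "relative_rate": rel,
                    }
                )
    return pd.DataFrame(rows)


def stratify_by_css(
    rates: pd.DataFrame,
    css_by_subject: pd.Series,
    value_col: str = "rate",
    threshold: float = 3.0,
):
    """Compare a rate distribution between mild (CSS < t) and severe (CSS >= t).

    Returns a dict with per-group n, median and IQR, and a two-sample
    rank-sum test when both groups are non-empty.  A subject with CSS
    exactly at the threshold lands in the severe group.
    """
    df = rates.copy()
    df["css"] = df["subject_id"].map(css_by_subject)
    if df["css"].isna().any():
        missing = sorted(df.loc[df["css"].isna(), "subject_id"].unique())
        raise ValueError(f"CSS missing for subjects: {missing}")
    mild = df.loc[df["css"] < threshold, value_col].to_numpy()
    severe = df.loc[df["css"] >= threshold, value_col].to_numpy()
    out = {
        "threshold": threshold,
        "groups": {
            "css_below": {"n": mild.size},
            "css_at_or_above": {"n": severe.size},
        },
        "test": None,
    }
    for name, g in (("css_below", mild), ("css_at_or_above", severe)):
        if g.size:
            q1, med, q3 = np.percentile(g, [25, 50, 75])
            out["groups"][name].update(median=float(med), iqr=(float(q1), float(q3)))
    if mild.size == 0 or severe.size == 0:
        warnings.warn(
            "one CSS stratum is empty; reporting summaries without a group test"
        )
        return out
    res = sps.mannwhitneyu(mild, severe, alternative="two-sided")
    out["test"] = TestResult(
        "rank_sum_css_strata", "U", float(res.statistic), float(res.pvalue),
        mild.size + severe.size,
    )
    return out
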