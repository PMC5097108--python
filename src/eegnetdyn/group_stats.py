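"""Cohort aggregation and mixed-design group statistics.

Per subject × condition, the stable-period analysis is summarized into the
number of stable periods, their mean duration, and per-metric means over
periods.  Each measure is then tested with a mixed two-way ANOVA — one
within-subject factor (condition: rest vs. event) and one between-subjects
factor (group) — followed by step-down independent-samples t tests (Welch
by default) within single conditions.

Subjects with no stable periods in a condition contribute a count of 0 but a
*missing* mean duration (the duration of nothing is undefined), and missing
values drop a subject from that measure's ANOVA with a logged warning.  No
multiple-testing correction is applied across the six network measures in
the primary report; a Holm-adjusted column is emitted alongside for
transparency.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

from .datatypes import AnovaResult, NetworkMetrics, StablePeriod

__all__ = [
    "summarize_subject",
    "build_cohort_table",
    "rm_anova",
    "stepdown_ttest",
    "holm_adjust",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["subject", "group", "condition", "measure", "value"]


def summarize_subject(
    periods: Sequence[StablePeriod],
    metrics: Sequence[NetworkMetrics],
    condition: str,
    subject: str = "s00",
    group: str = "",
) -> pd.DataFrame:
    """Tidy rows of per-subject summary measures for one condition.

    Emits ``n_stable`` (count of stable periods), ``mean_duration`` (s; NaN
    when there are no periods) and the mean of each graph measure over the
    subject's averaged stable networks.
    """
    if len(metrics) != len(periods):
        raise ValueError("need one NetworkMetrics per StablePeriod")
    rows = [
        {"measure": "n_stable", "value": float(len(periods))},
        {
            "measure": "mean_duration",
            "value": float(np.mean([p.duration for p in periods])) if periods else np.nan,
        },
    ]
    for name in NetworkMetrics._FIELDS:
        vals = [m.as_dict()[name] for m in metrics]
        rows.append(
            {"measure": name, "value": float(np.mean(vals)) if vals else np.nan}
        )
    df = pd.DataFrame(rows)
    df.insert(0, "condition", condition)
    df.insert(0, "group", group)
    df.insert(0, "subject", subject)
    return df


def build_cohort_table(frames: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-subject summaries into one cohort table."""
    table = pd.concat(frames, ignore_index=True)
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")
    return table


def _complete_wide(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    sub = table[table["measure"] == measure]
    if sub.empty:
        raise ValueError(f"measure {measure!r} not present in table")
    wide = sub.pivot_table(
        index=["subject", "group"], columns="condition", values="value", aggfunc="first"
    )
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.warning(
            "measure %s: dropped %d subjects with incomplete condition data",
            measure,
            n_dropped,
        )
    return complete.reset_index()


def rm_anova(table: pd.DataFrame, measure: str) -> list[AnovaResult]:
    """Mixed two-way ANOVA for one measure.

    Within factor: condition; between factor: group.  Subjects missing a
    condition are dropped (with a warning); each group must retain at least
    two complete subjects.
    """
    wide = _complete_wide(table, measure)
    counts = wide.groupby("group").size()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError(
            f"measure {measure!r}: every group needs >= 2 complete subjects, got "
            f"{counts.to_dict()}"
        )
    long = wide.melt(
        id_vars=["subject", "group"], var_name="condition", value_name="value"
    )
    aov = pg.mixed_anova(
        data=long, dv="value", within="condition", subject="subject", between="group"
    )
    name_map = {"group": "group", "condition": "condition", "Interaction": "condition x group"}
    results = []
    for _, row in aov.iterrows():
        results.append(
            AnovaResult(
                effect=name_map[row["Source"]],
                F=float(row["F"]),
                df1=int(row["DF1"]),
                df2=int(row["DF2"]),
                p=float(row["p_unc"]),
            )
        )
    return results


def stepdown_ttest(
    table: pd.DataFrame,
    measure: str,
    condition: str,
    equal_var: bool = False,
) -> tuple[float, float, float]:
    """Independent-samples t test between groups within one condition.

    Welch's correction is the default (``equal_var=False``); returns
    ``(t, df, p)``.  Identical group values give ``t = 0, p = 1``.
    """
    sub = table[(table["measure"] == measure) & (table["condition"] == condition)]
    sub = sub.dropna(subset=["value"])
    groups = sorted(sub["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    a = sub.loc[sub["group"] == groups[0], "value"].to_numpy()
    b = sub.loc[sub["group"] == groups[1], "value"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 subjects")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (transparency report)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
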