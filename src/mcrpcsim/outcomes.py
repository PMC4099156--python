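"""Result tables: per-line costs, totals, national extrapolation, figure data.

The three published result views are reproduced as pandas DataFrames:
treatment sequences with durations and survival, per-line cost by
medication category (among patients receiving that line), and total /
monthly cost by category with the national extrapolation (per-patient
mean x the 4,000-patient annual Canadian mCRPC cohort).  Monthly cost
per patient is the mean total divided by the mean mCRPC duration.
IQRs are 25th/75th percentiles with linear interpolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import CohortRecords, CohortSummary, ReplicationSummary

__all__ = [
    "utilization_and_survival_table",
    "per_state_cost_table",
    "total_cost_table",
    "cumulative_cost_by_last_line",
    "plot_cumulative_cost",
]

_CATEGORIES = ("primary", "castration", "bone", "total")


def utilization_and_survival_table(summary: CohortSummary) -> pd.DataFrame:
    """Per-line utilization, treatment duration and survival from entry."""
    df = summary.states
    out = pd.DataFrame(
        {
            "pct_receiving": 100.0 * df["utilization"],
            "dur_mean": df["dur_mean"],
            "dur_median": df["dur_median"],
            "dur_q25": df["dur_q25"],
            "dur_q75": df["dur_q75"],
            "surv_mean": df["surv_mean"],
            "surv_median": df["surv_median"],
            "surv_q25": df["surv_q25"],
            "surv_q75": df["surv_q75"],
        }
    )
    out.index.name = "state"
    return out


def per_state_cost_table(summary: CohortSummary) -> pd.DataFrame:
    """Mean and median cost per medication category, by line of treatment.

    Statistics are computed among patients who entered each line; the
    primary column covers the line's primary drug with co- and
    premedications, castration and bone columns the supportive
    therapies accrued while in that line.
    """
    cols = {}
    for cat in _CATEGORIES:
        for stat in ("mean", "median", "q25", "q75"):
            cols[f"{cat}_{stat}"] = summary.states[f"{cat}_{stat}"]
    return pd.DataFrame(cols)


def total_cost_table(summary: CohortSummary,
                     replications: dict[str, ReplicationSummary] | None = None
                     ) -> pd.DataFrame:
    """Total, monthly and national cost of the mCRPC period by category.

    ``replications`` optionally supplies replicate-sample CIs keyed by
    category.  The national total is the per-patient mean times the
    annual national cohort, exactly; category shares are percentages of
    the mean total cost.
    """
    totals = summary.totals
    grand = totals.loc["total", "mean"]
    rows = []
    for cat in _CATEGORIES:
        mean = totals.loc[cat, "mean"]
        row = {
            "category": cat,
            "mean": mean,
            "median": totals.loc[cat, "median"],
            "iqr_low": totals.loc[cat, "q25"],
            "iqr_high": totals.loc[cat, "q75"],
            "monthly_mean": mean / summary.mcrpc_months_mean,
            "national_total": mean * summary.national_cohort,
            "share_pct": 100.0 * mean / grand if grand else 0.0,
        }
        if replications and cat in replications:
            row["ci_low"], row["ci_high"] = replications[cat].ci95
        rows.append(row)
    return pd.DataFrame(rows).set_index("category")


def cumulative_cost_by_last_line(records: CohortRecords) -> pd.DataFrame:
    """Mean cumulative cost per category, grouped by last line received.

    The groups partition the cohort; weighting the group means by group
    frequency recovers the overall mean exactly.
    """
    spec = records.spec
    costs = records.category_costs()
    rows = []
    for s, name in enumerate(spec.state_names):
        mask = records.last_state == s
        n = int(mask.sum())
        if n == 0:
            continue
        row = {"last_line": name, "n": n, "fraction": n / records.n}
        for cat in _CATEGORIES:
            row[cat] = float(costs[cat][mask].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("last_line")


def plot_cumulative_cost(table: pd.DataFrame, ax=None):
    """Stacked-bar chart of mean cumulative cost by last line received."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(len(table))
    for cat, color in zip(("castration", "bone", "primary"), ("#666", "#999", "#37a")):
        ax.bar(table.index, table[cat], bottom=bottom, label=cat, color=color)
        bottom += table[cat].to_numpy()
    ax.set_ylabel("mean cumulative cost (2013 CAD)")
    ax.set_xlabel("last line of treatment received")
    ax.legend()
    return ax
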