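"""Biceps motor-neuron pool mapping over spinal segments C2–T2.

Retrograde CTB tracing labels the spinal motor neurons innervating the
biceps; counting them per spinal level in uninjured (naive) and
C7-contused (sci) animals maps where the pool sits and how much of it the
injury removes.  The packaged count table (8 animals x 9 levels, wide
layout with per-animal totals) ships with the package; the same analysis
runs on any table in that layout.

Group comparisons use the exact Mann–Whitney U test per level — at 5 vs 3
animals the full 56-assignment enumeration is both feasible and the only
honest p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import MN_GROUPS, SPINAL_LEVELS
from .stats import TestResult, mann_whitney_exact

_FIXTURE = "mn_counts.csv"


def load_counts(path: str | Path | None = None) -> pd.DataFrame:
    """Load a motor-neuron count table into tidy long form.

    Input is wide (one row per animal, one column per spinal level, plus a
    ``total`` column that is verified against the level sum).  Returns a
    long table (animal_id, group, level, count).  With no path the
    packaged reference table is used.
    """
    if path is None:
        src = resources.files("mepkit.data").joinpath(_FIXTURE)
        wide = pd.read_csv(src.open())
    else:
        wide = pd.read_csv(path)
    missing = [lv for lv in SPINAL_LEVELS if lv not in wide.columns]
    if missing:
        raise ValueError(f"count table lacks level columns {missing}")
    counts = wide[list(SPINAL_LEVELS)].to_numpy()
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    if "total" in wide.columns and not np.array_equal(
        counts.sum(axis=1), wide["total"].to_numpy()
    ):
        raise ValueError("per-animal totals do not match the level sums")

    long = wide.melt(
        id_vars=["animal_id", "group"],
        value_vars=list(SPINAL_LEVELS),
        var_name="level",
        value_name="count",
    )
    long["count"] = long["count"].astype(int)
    long["level"] = pd.Categorical(long["level"], categories=SPINAL_LEVELS, ordered=True)
    return long.sort_values(["group", "animal_id", "level"]).reset_index(drop=True)


def load_reference_counts() -> pd.DataFrame:
    """The packaged reference counts (5 naive, 3 injured animals)."""
    return load_counts(None)


@dataclass
class CountSummary:
    per_level: pd.DataFrame  # group, level, mean, sd, n
    animal_totals: pd.DataFrame  # animal_id, group, total
    group_totals: pd.DataFrame  # group, mean, sd, n


def summarize_counts(table: pd.DataFrame) -> CountSummary:
    """Per-(group, level) mean and sample SD, plus per-animal totals.

    SD uses the n-1 denominator; a single-animal group reports NaN SD.
    """
    if table.empty:
        raise ValueError("empty count table")
    per_level = (
        table.groupby(["group", "level"], observed=True)["count"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    animal_totals = (
        table.groupby(["animal_id", "group"], observed=True)["count"]
        .sum()
        .rename("total")
        .reset_index()
    )
    group_totals = (
        animal_totals.groupby("group", observed=True)["total"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    return CountSummary(per_level, animal_totals, group_totals)


def compare_levels(
    table: pd.DataFrame, groups: tuple[str, str] = MN_GROUPS
) -> pd.DataFrame:
    """Exact Mann–Whitney U per spinal level between two groups.

    Levels where every animal in both groups has zero counts are not
    testable (no variation to rank) and are flagged instead of tested.
    """
    g1, g2 = groups
    present = set(table["group"].unique())
    if not {g1, g2} <= present:
        raise ValueError(f"groups {groups} not both present (have {sorted(present)})")
    rows = []
    for level in SPINAL_LEVELS:
        sub = table[table["level"] == level]
        x = sub.loc[sub["group"] == g1, "count"].to_numpy()
        y = sub.loc[sub["group"] == g2, "count"].to_numpy()
        if x.size == 0 or y.size == 0:
            continue
        if np.all(x == 0) and np.all(y == 0):
            rows.append({"level": level, "testable": False, "U": np.nan, "p": np.nan})
            continue
        res: TestResult = mann_whitney_exact(x, y)
        rows.append({"level": level, "testable": True, "U": res.statistic, "p": res.p})
    return pd.DataFrame(rows)


def heatmap_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Groups x levels matrix of mean counts, ordered C2 to T2.

    Row sums equal the group-mean totals by linearity of the mean.
    """
    mat = (
        table.pivot_table(index="group", columns="level", values="count", observed=True)
        .reindex(columns=list(SPINAL_LEVELS))
    )
    mat.columns = list(mat.columns)
    return mat
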