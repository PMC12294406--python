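"""Merge trajectory assignments with SDOH and health tables.

All tables are keyed by the 11-digit tract identifier.  The merge is an
inner join (the analysis covers only tracts present in every source), with
every drop recorded in the exclusion ledger.  Population-density quartiles
(Q4 = highest = model reference) are attached from the composition panel.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .trajectory import ExclusionLedger

__all__ = [
    "combine_assignments",
    "merge_tables",
    "assign_density_quartiles",
    "build_analytic_table",
]

QUARTILE_LEVELS = ("Q1", "Q2", "Q3", "Q4")


def _require_unique(table: pd.DataFrame, name: str) -> None:
    if "tract_id" not in table.columns:
        raise ValueError(f"table {name!r} lacks a tract_id column")
    if table["tract_id"].duplicated().any():
        dup = table.loc[table["tract_id"].duplicated(), "tract_id"].iloc[0]
        raise ValueError(f"duplicate tract_id {dup!r} in table {name!r}")


def combine_assignments(
    poverty: pd.DataFrame,
    share: pd.DataFrame,
    ledger: Optional[ExclusionLedger] = None,
) -> Tuple[pd.DataFrame, ExclusionLedger]:
    """Join poverty and group-share assignments, keeping labeled tracts only.

    A tract excluded under either variable (missing data or undefined
    pattern) is dropped, with counts recorded in filter order.
    """
    ledger = ledger if ledger is not None else ExclusionLedger()
    _require_unique(poverty, "poverty assignments")
    _require_unique(share, "share assignments")
    n_in = len(poverty)
    pov_ok = poverty[poverty["trajectory"] != ""]
    ledger.add("combine", "excluded_poverty", n_in - len(pov_ok))
    merged = pov_ok.merge(
        share[share["trajectory"] != ""][["tract_id", "trajectory"]],
        on="tract_id",
        how="inner",
        suffixes=("_poverty", "_share"),
    )
    ledger.add("combine", "excluded_share", len(pov_ok) - len(merged))
    out = merged.rename(
        columns={
            "trajectory_poverty": "poverty_trajectory",
            "trajectory_share": "share_trajectory",
        }
    )[["tract_id", "poverty_trajectory", "share_trajectory"]]
    return out, ledger


def merge_tables(
    assignments: pd.DataFrame,
    sdoh_table: pd.DataFrame,
    health_table: pd.DataFrame,
    ledger: Optional[ExclusionLedger] = None,
) -> Tuple[pd.DataFrame, ExclusionLedger]:
    """Inner-join assignments with the SDOH and health tables.

    Tracts missing from either measure table are logged as
    ``not_in_sdoh`` / ``not_in_health`` (in that order).  Duplicate keys or
    an empty result abort.
    """
    ledger = ledger if ledger is not None else ExclusionLedger()
    _require_unique(assignments, "assignments")
    _require_unique(sdoh_table, "sdoh")
    _require_unique(health_table, "health")

    step1 = assignments.merge(sdoh_table, on="tract_id", how="inner")
    not_in_sdoh = len(assignments) - len(step1)
    ledger.add("merge", "not_in_sdoh", not_in_sdoh)
    step2 = step1.merge(health_table, on="tract_id", how="inner")
    not_in_health = len(step1) - len(step2)
    ledger.add("merge", "not_in_health", not_in_health)
    if step2.empty:
        raise ValueError("merge produced zero surviving tracts")
    assert len(assignments) == len(step2) + not_in_sdoh + not_in_health
    return step2.reset_index(drop=True), ledger


def assign_density_quartiles(density: pd.Series) -> pd.Series:
    """Empirical density quartiles Q1 (lowest) … Q4 (highest).

    Cutpoints are the 25/50/75th linear-interpolation percentiles; a value
    at or below a cutpoint falls in the lower quartile, so equal values
    always share a quartile.  Labels depend only on ranks, hence are
    invariant under any strictly increasing transform of density.
    """
    vals = pd.to_numeric(density, errors="coerce")
    if vals.isna().any():
        raise ValueError("density contains missing values")
    arr = vals.to_numpy(dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 tracts to form density quartiles")
    if np.any(arr <= 0.0):
        raise ValueError("population density must be positive")
    cuts = np.percentile(arr, [25.0, 50.0, 75.0])
    idx = np.searchsorted(cuts, arr, side="left")
    return pd.Series(np.array(QUARTILE_LEVELS, dtype=object)[idx], index=density.index)


def build_analytic_table(
    panel: pd.DataFrame,
    poverty_assignments: pd.DataFrame,
    share_assignments: pd.DataFrame,
    sdoh_table: pd.DataFrame,
    health_table: pd.DataFrame,
) -> Tuple[pd.DataFrame, ExclusionLedger]:
    """Full linkage: combine labels, merge measures, attach quartiles.

    Density quartiles are computed on the final analytic set, i.e. the
    tracts actually modeled.
    """
    assignments, ledger = combine_assignments(poverty_assignments, share_assignments)
    table, ledger = merge_tables(assignments, sdoh_table, health_table, ledger)
    density = panel.set_index("tract_id")["density_2010"]
    table = table.assign(density_2010=table["tract_id"].map(density))
    if table["density_2010"].isna().any():
        raise ValueError("analytic tracts missing from the composition panel")
    table["density_quartile"] = assign_density_quartiles(table["density_2010"])
    ledger.check_conservation(len(poverty_assignments), len(table))
    return table, ledger
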