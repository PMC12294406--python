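"""Trajectory classification of tract composition series.

Each census tract carries a composition percentage (poverty, or the share of
a racial/ethnic group) at three decennial time points.  Each value is first
*categorized* into one of three ordered levels — LOW, MODERATE, HIGH — using
either fixed percentage bands (the a-priori poverty bands 0–5%, 5–20%, >20%)
or empirical tertiles of the observed distribution.  The resulting ordered
triple of categories is then mapped to one of five a-priori trajectory
labels (long-term low / moderate / high, increasing, decreasing) or to an
UNDEFINED sink for patterns with no discernible direction.

Two pattern rules are supported:

* ``MONOTONE`` (default): a non-constant triple is increasing only if its
  categories never step down (c1 <= c2 <= c3 with c1 < c3), and symmetrically
  for decreasing; every non-monotone triple is UNDEFINED.  The 27 possible
  triples split 3 constant / 7 increasing / 7 decreasing / 10 undefined.
* ``ENDPOINT``: direction is read off the first and last category alone;
  only "there-and-back" triples (c1 == c3 != c2) are UNDEFINED.  Split:
  3 / 9 / 9 / 6.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Category",
    "TrajectoryLabel",
    "FIVE_LABELS",
    "PatternRule",
    "CategorizationScheme",
    "ExclusionLedger",
    "categorize",
    "categorize_series",
    "resolve_tertiles",
    "classify_pattern",
    "classify_panel",
    "YEARS",
]

#: Census years of the composition panel, oldest first.
YEARS: Tuple[int, int, int] = (1990, 2000, 2010)


class Category(enum.IntEnum):
    """Ordered composition level; LOW < MODERATE < HIGH."""

    LOW = 0
    MODERATE = 1
    HIGH = 2

    def __str__(self) -> str:  # CSV-friendly
        return self.name.lower()


class TrajectoryLabel(str, enum.Enum):
    """Five a-priori 20-year trajectories plus the undefined sink."""

    LONG_TERM_LOW = "long_term_low"
    LONG_TERM_MODERATE = "long_term_moderate"
    LONG_TERM_HIGH = "long_term_high"
    INCREASING = "increasing"
    DECREASING = "decreasing"
    UNDEFINED = "undefined"

    def __str__(self) -> str:
        return self.value


#: The five analyzable labels, in reporting order.
FIVE_LABELS: Tuple[TrajectoryLabel, ...] = (
    TrajectoryLabel.LONG_TERM_LOW,
    TrajectoryLabel.LONG_TERM_MODERATE,
    TrajectoryLabel.LONG_TERM_HIGH,
    TrajectoryLabel.INCREASING,
    TrajectoryLabel.DECREASING,
)

_CONSTANT_LABEL = {
    Category.LOW: TrajectoryLabel.LONG_TERM_LOW,
    Category.MODERATE: TrajectoryLabel.LONG_TERM_MODERATE,
    Category.HIGH: TrajectoryLabel.LONG_TERM_HIGH,
}


class PatternRule(str, enum.Enum):
    """How a non-constant category triple is given a direction."""

    MONOTONE = "monotone"
    ENDPOINT = "endpoint"


@dataclass(frozen=True)
class CategorizationScheme:
    """How raw percentages are cut into the three ordered levels.

    ``fixed`` mode uses ``edges`` as hard thresholds; a value ``v`` is LOW if
    ``v <= edges[0]``, MODERATE if ``edges[0] < v <= edges[1]``, HIGH
    otherwise (so the printed bands "0–5%, 5–20%, >20%" are disjoint).
    ``tertile`` mode derives the two edges from the data, either within each
    year (``per_year``, default) or from all years pooled.
    """

    mode: str = "fixed"  # "fixed" | "tertile"
    edges: Tuple[float, float] = (5.0, 20.0)
    tertile_scope: str = "per_year"  # "per_year" | "pooled"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "tertile"):
            raise ValueError(f"unknown scheme mode {self.mode!r}")
        if self.tertile_scope not in ("per_year", "pooled"):
            raise ValueError(f"unknown tertile scope {self.tertile_scope!r}")
        e1, e2 = self.edges
        if not (0.0 < e1 < e2 < 100.0):
            raise ValueError(f"band edges must satisfy 0 < e1 < e2 < 100, got {self.edges}")


@dataclass
class ExclusionLedger:
    """Ordered, auditable record of tracts dropped at each filter stage."""

    entries: list = field(default_factory=list)  # (stage, reason, count)

    def add(self, stage: str, reason: str, count: int) -> None:
        if count < 0:
            raise ValueError("exclusion counts must be non-negative")
        self.entries.append((stage, reason, int(count)))

    @property
    def total_excluded(self) -> int:
        return sum(c for _, _, c in self.entries)

    def count(self, reason: str) -> int:
        return sum(c for _, r, c in self.entries if r == reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["stage", "reason", "count"])

    def check_conservation(self, n_in: int, n_out: int) -> None:
        """Raise unless input = output + total excluded."""
        if n_in != n_out + self.total_excluded:
            raise AssertionError(
                f"ledger conservation violated: {n_in} in, {n_out} out, "
                f"{self.total_excluded} excluded"
            )


def categorize(value: float, edges: Tuple[float, float] = (5.0, 20.0)) -> Optional[Category]:
    """Cut one percentage into LOW / MODERATE / HIGH.

    Missing values (None or NaN) propagate as ``None``.  Values outside
    [0, 100] are rejected.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    v = float(value)
    if not (0.0 <= v <= 100.0):
        raise ValueError(f"composition percentage {v!r} outside [0, 100]")
    e1, e2 = edges
    if v <= e1:
        return Category.LOW
    if v <= e2:
        return Category.MODERATE
    return Category.HIGH


def categorize_series(values: pd.Series, edges: Tuple[float, float]) -> pd.Series:
    """Vectorized :func:`categorize`; returns a Series of Category / NaN."""
    arr = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
    finite = np.isfinite(arr)
    if np.any((arr[finite] < 0.0) | (arr[finite] > 100.0)):
        bad = arr[finite][(arr[finite] < 0.0) | (arr[finite] > 100.0)][0]
        raise ValueError(f"composition percentage {bad!r} outside [0, 100]")
    e1, e2 = edges
    out = np.full(arr.shape, np.nan, dtype=object)
    out[finite & (arr <= e1)] = Category.LOW
    out[finite & (arr > e1) & (arr <= e2)] = Category.MODERATE
    out[finite & (arr > e2)] = Category.HIGH
    return pd.Series(out, index=values.index)


def resolve_tertiles(
    values_by_year: Mapping[int, Sequence[float]],
    scope: str = "per_year",
) -> Dict[int, Tuple[float, float]]:
    """Compute tertile cutpoints (33.33rd / 66.67th percentiles).

    ``per_year`` computes cutpoints within each year's distribution;
    ``pooled`` computes one pair from all years combined and applies it to
    every year.  Percentiles use linear interpolation (the package-wide
    convention, shared with medians and density quartiles).
    """
    cleaned: Dict[int, np.ndarray] = {}
    for year, vals in values_by_year.items():
        arr = np.asarray(pd.to_numeric(pd.Series(vals), errors="coerce"), dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 3:
            raise ValueError(f"need >=3 non-missing values to form tertiles for year {year}")
        cleaned[year] = arr
    if scope == "pooled":
        pooled = np.concatenate(list(cleaned.values()))
        e1, e2 = np.percentile(pooled, [100.0 / 3.0, 200.0 / 3.0])
        return {year: (float(e1), float(e2)) for year in cleaned}
    if scope != "per_year":
        raise ValueError(f"unknown tertile scope {scope!r}")
    out: Dict[int, Tuple[float, float]] = {}
    for year, arr in cleaned.items():
        e1, e2 = np.percentile(arr, [100.0 / 3.0, 200.0 / 3.0])
        out[year] = (float(e1), float(e2))
    return out


def classify_pattern(
    c1: Category,
    c2: Category,
    c3: Category,
    rule: PatternRule = PatternRule.MONOTONE,
) -> TrajectoryLabel:
    """Map one ordered category triple to a trajectory label.

    Raises if any category is missing — callers must route tracts with
    missing data to the MISSING_DATA exclusion before classifying.
    """
    if c1 is None or c2 is None or c3 is None:
        raise ValueError("cannot classify a pattern with missing categories")
    rule = PatternRule(rule)
    if c1 == c2 == c3:
        return _CONSTANT_LABEL[c1]
    if rule is PatternRule.MONOTONE:
        if c1 <= c2 <= c3 and c1 < c3:
            return TrajectoryLabel.INCREASING
        if c1 >= c2 >= c3 and c1 > c3:
            return TrajectoryLabel.DECREASING
        return TrajectoryLabel.UNDEFINED
    # ENDPOINT: direction from first vs. last category only
    if c3 > c1:
        return TrajectoryLabel.INCREASING
    if c3 < c1:
        return TrajectoryLabel.DECREASING
    return TrajectoryLabel.UNDEFINED


def undefined_patterns(rule: PatternRule) -> Tuple[Tuple[Category, Category, Category], ...]:
    """All category triples the given rule maps to UNDEFINED."""
    rule = PatternRule(rule)
    triples = []
    for c1 in Category:
        for c2 in Category:
            for c3 in Category:
                if classify_pattern(c1, c2, c3, rule) is TrajectoryLabel.UNDEFINED:
                    triples.append((c1, c2, c3))
    return tuple(triples)


def _panel_columns(variable: str) -> Tuple[str, ...]:
    prefix = {"poverty": "pov", "share": "share"}.get(variable)
    if prefix is None:
        raise ValueError(f"variable must be 'poverty' or 'share', got {variable!r}")
    return tuple(f"{prefix}_{y}" for y in YEARS)


def classify_panel(
    panel: pd.DataFrame,
    variable: str = "poverty",
    scheme: CategorizationScheme | None = None,
    rule: PatternRule = PatternRule.MONOTONE,
) -> Tuple[pd.DataFrame, ExclusionLedger]:
    """Classify every tract in a composition panel.

    Parameters
    ----------
    panel:
        One row per tract with columns ``tract_id`` and either
        ``pov_1990/pov_2000/pov_2010`` or ``share_1990/share_2000/share_2010``.
    variable:
        ``"poverty"`` or ``"share"``.
    scheme:
        Categorization scheme; defaults to the fixed poverty bands (5, 20).
    rule:
        Pattern rule for non-constant triples.

    Returns
    -------
    (assignments, ledger):
        ``assignments`` has one row per input tract: the per-year category,
        the trajectory label for analyzable tracts, and an
        ``exclusion_reason`` (``missing_data`` before ``undefined_pattern``)
        for excluded ones.  The ledger records the two exclusion counts in
        filter order and satisfies the conservation identity.
    """
    if panel.empty:
        raise ValueError("panel is empty")
    if panel["tract_id"].duplicated().any():
        dup = panel.loc[panel["tract_id"].duplicated(), "tract_id"].iloc[0]
        raise ValueError(f"duplicate tract_id in panel: {dup!r}")
    scheme = scheme or CategorizationScheme()
    rule = PatternRule(rule)
    cols = _panel_columns(variable)

    if scheme.mode == "fixed":
        edges_by_year = {y: scheme.edges for y in YEARS}
    else:
        values_by_year = {y: panel[c] for y, c in zip(YEARS, cols)}
        edges_by_year = resolve_tertiles(values_by_year, scheme.tertile_scope)

    cats = {
        y: categorize_series(panel[c], edges_by_year[y]) for y, c in zip(YEARS, cols)
    }
    cat_frame = pd.DataFrame(cats)
    missing = cat_frame.isna().any(axis=1)

    labels = np.full(len(panel), "", dtype=object)
    reasons = np.full(len(panel), "", dtype=object)
    reasons[missing.to_numpy()] = "missing_data"

    complete_idx = np.flatnonzero(~missing.to_numpy())
    for i in complete_idx:
        lab = classify_pattern(
            cat_frame.iloc[i, 0], cat_frame.iloc[i, 1], cat_frame.iloc[i, 2], rule
        )
        if lab is TrajectoryLabel.UNDEFINED:
            reasons[i] = "undefined_pattern"
        else:
            labels[i] = lab.value

    assignments = pd.DataFrame(
        {
            "tract_id": panel["tract_id"].to_numpy(),
            "cat_1990": [("" if c is np.nan or not isinstance(c, Category) else str(c)) for c in cat_frame[1990]],
            "cat_2000": [("" if c is np.nan or not isinstance(c, Category) else str(c)) for c in cat_frame[2000]],
            "cat_2010": [("" if c is np.nan or not isinstance(c, Category) else str(c)) for c in cat_frame[2010]],
            "trajectory": labels,
            "exclusion_reason": reasons,
        }
    )

    ledger = ExclusionLedger()
    stage = f"classify_{variable}"
    ledger.add(stage, "missing_data", int(missing.sum()))
    ledger.add(stage, "undefined_pattern", int((reasons == "undefined_pattern").sum()))
    n_labeled = int((labels != "").sum())
    ledger.check_conservation(len(panel), n_labeled)
    return assignments, ledger
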