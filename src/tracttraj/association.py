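"""The association battery: summaries, ANOVA screens, adjusted linear
models, and the ancillary negative-trajectory logistic model.

For each exposure (poverty trajectories, reference long-term low; group-share
trajectories, reference long-term high) and each of the 26 tract-level
outcomes, the battery runs a one-way ANOVA and an ordinary-least-squares
model of the (possibly log-transformed) outcome on four trajectory dummies
plus three population-density-quartile dummies (reference Q4, the highest
quartile).  Significance uses the fixed family-wise threshold p <= 0.001
(a Bonferroni-style guard against the large number of tests).  Classical
(non-robust) standard errors are reported, with two-sided t tests.

The ancillary model is a logistic regression of the "negative poverty
trajectory" indicator (long-term high or increasing poverty) on the
group-share trajectory dummies, with Wald 95% confidence intervals on the
odds-ratio scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .linkage import QUARTILE_LEVELS
from .measures import DEFAULT_LOG_OFFSETS, OUTCOME_MEASURES, get_measure
from .trajectory import FIVE_LABELS, TrajectoryLabel

__all__ = [
    "ALPHA_BONFERRONI",
    "NEGATIVE_POVERTY_LABELS",
    "LogTransformRegistry",
    "TermEstimate",
    "ModelResult",
    "AnovaResult",
    "OddsRatioResult",
    "BatteryResult",
    "default_reference",
    "summarize",
    "anova_by_trajectory",
    "trajectory_design",
    "fit_trajectory_model",
    "run_battery",
    "fit_negative_trajectory_logistic",
    "ols_many",
]

#: Fixed family-wise significance threshold.
ALPHA_BONFERRONI = 0.001

#: Labels composing the "negative poverty trajectory" composite outcome.
NEGATIVE_POVERTY_LABELS = (
    TrajectoryLabel.LONG_TERM_HIGH.value,
    TrajectoryLabel.INCREASING.value,
)

_Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class LogTransformRegistry:
    """Outcomes log-transformed before modeling, with per-name offsets.

    The default membership is the six right-skewed measures (the two
    healthcare distances, median home value, crowded housing, public
    assistance, limited English proficiency); strictly positive measures use
    offset 0 and the zero-containing percentages use offset 1.
    """

    offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_OFFSETS)
    )

    def __post_init__(self) -> None:
        for name, off in self.offsets.items():
            if off < 0:
                raise ValueError(f"offset for {name!r} must be non-negative")

    @classmethod
    def from_names(cls, names: Iterable[str], offset: float = 0.0) -> "LogTransformRegistry":
        """Registry with one common offset for every listed name."""
        return cls({n: float(offset) for n in names})

    @property
    def names(self) -> frozenset:
        return frozenset(self.offsets)

    def __contains__(self, name: str) -> bool:
        return name in self.offsets

    def transform(self, name: str, values: np.ndarray) -> Tuple[np.ndarray, bool]:
        """Return (modeling-scale values, whether a log was applied)."""
        arr = np.asarray(values, dtype=float)
        if name not in self.offsets:
            return arr, False
        shifted = arr + self.offsets[name]
        if np.any(shifted[np.isfinite(shifted)] <= 0.0):
            raise ValueError(
                f"cannot log-transform {name!r}: values <= -offset present"
            )
        return np.log(shifted), True


def default_reference(exposure: str) -> TrajectoryLabel:
    """Published reference categories: long-term low for poverty models,
    long-term high for group-share models."""
    if exposure == "poverty":
        return TrajectoryLabel.LONG_TERM_LOW
    if exposure == "share":
        return TrajectoryLabel.LONG_TERM_HIGH
    raise ValueError(f"exposure must be 'poverty' or 'share', got {exposure!r}")


@dataclass(frozen=True)
class TermEstimate:
    term: str
    beta: float
    se: float
    p: float
    significant: bool


@dataclass
class ModelResult:
    """One adjusted linear model (one outcome x one exposure)."""

    outcome: str
    exposure: str
    reference: str
    terms: List[TermEstimate]
    intercept: float
    r_squared: float
    f_stat: float
    f_p: float
    n: int
    log_transformed: bool
    alpha: float
    dropped: List[str] = field(default_factory=list)

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def to_row(self) -> Dict[str, float]:
        row: Dict[str, float] = {
            "outcome": self.outcome,
            "exposure": self.exposure,
            "log_transformed": self.log_transformed,
            "n": self.n,
        }
        for t in self.terms:
            row[f"{t.term}_beta"] = t.beta
            row[f"{t.term}_se"] = t.se
            row[f"{t.term}_p"] = t.p
            row[f"{t.term}_sig"] = int(t.significant)
        row["r_squared"] = self.r_squared
        row["f_stat"] = self.f_stat
        row["f_p"] = self.f_p
        return row


@dataclass(frozen=True)
class AnovaResult:
    outcome: str
    exposure: str
    f_stat: float
    p: float
    group_count: int
    n: int


@dataclass
class OddsRatioResult:
    """Odds ratios for the negative-poverty-trajectory logistic model."""

    reference: str
    levels: List[str]
    odds_ratios: Dict[str, float]
    ci_lower: Dict[str, float]
    ci_upper: Dict[str, float]
    n: int
    separation: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.levels,
                "odds_ratio": [self.odds_ratios[l] for l in self.levels],
                "ci_lower": [self.ci_lower[l] for l in self.levels],
                "ci_upper": [self.ci_upper[l] for l in self.levels],
                "reference": self.reference,
                "separation_flag": self.separation,
            }
        )


def summarize(
    table: pd.DataFrame, measures: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Descriptive summary: median (range) per measure, percent per label.

    Medians use the same linear-interpolation percentile convention as the
    tertile and quartile cutpoints.  All-missing columns are reported with
    missing statistics rather than silently dropped.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty table")
    measures = list(measures) if measures is not None else [
        m for m in OUTCOME_MEASURES if m in table.columns
    ]
    rows = []
    for name in measures:
        vals = pd.to_numeric(table[name], errors="coerce").to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            rows.append((get_measure(name).group, name, np.nan, np.nan, np.nan, np.nan))
            continue
        med = float(np.percentile(vals, 50.0))
        rows.append(
            (get_measure(name).group, name, med, float(vals.min()), float(vals.max()), np.nan)
        )
    for col, section in (
        ("poverty_trajectory", "poverty_trajectories"),
        ("share_trajectory", "share_trajectories"),
    ):
        if col not in table.columns:
            continue
        counts = table[col].value_counts()
        total = counts.sum()
        for lab in FIVE_LABELS:
            pct = 100.0 * counts.get(lab.value, 0) / total
            rows.append((section, lab.value, np.nan, np.nan, np.nan, float(pct)))
    return pd.DataFrame(
        rows, columns=["section", "variable", "median", "range_low", "range_high", "percent"]
    )


def anova_by_trajectory(values: Sequence[float], labels: Sequence[str]) -> AnovaResult:
    """One-way fixed-effects ANOVA of an outcome across trajectory groups."""
    vals = pd.to_numeric(pd.Series(values), errors="coerce").to_numpy(dtype=float)
    labs = np.asarray(labels, dtype=object)
    keep = np.isfinite(vals)
    vals, labs = vals[keep], labs[keep]
    groups = [vals[labs == g] for g in pd.unique(labs)]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 non-empty groups")
    f_stat, p = stats.f_oneway(*groups)
    return AnovaResult(
        outcome="", exposure="", f_stat=float(f_stat), p=float(p),
        group_count=len(groups), n=int(vals.size),
    )


def trajectory_design(
    table: pd.DataFrame,
    exposure: str = "poverty",
    reference: Optional[TrajectoryLabel] = None,
) -> Tuple[pd.DataFrame, List[str]]:
    """Dummy design matrix: intercept, 4 trajectory dummies, 3 quartile dummies.

    Returns the design and the ordered term names (reference levels omitted:
    the exposure reference and density quartile Q4).
    """
    reference = reference or default_reference(exposure)
    col = f"{exposure}_trajectory"
    if col not in table.columns:
        raise ValueError(f"table lacks column {col!r}")
    if not (table[col] == reference.value).any():
        raise ValueError(f"reference level {reference.value!r} absent from {col!r}")
    terms: List[str] = []
    X = pd.DataFrame(index=table.index)
    X["const"] = 1.0
    for lab in FIVE_LABELS:
        if lab is reference:
            continue
        X[lab.value] = (table[col] == lab.value).astype(float)
        terms.append(lab.value)
    for q in QUARTILE_LEVELS[:-1]:
        X[q] = (table["density_quartile"] == q).astype(float)
        terms.append(q)
    return X, terms


def fit_trajectory_model(
    table: pd.DataFrame,
    outcome: str,
    exposure: str = "poverty",
    registry: Optional[LogTransformRegistry] = None,
    reference: Optional[TrajectoryLabel] = None,
    alpha: float = ALPHA_BONFERRONI,
) -> ModelResult:
    """OLS of one outcome on trajectory + density-quartile dummies.

    The outcome is log-transformed iff it is in the registry.  Missing
    outcome values are dropped (complete-case).  Empty or collinear dummy
    columns are dropped with a warning recorded in the result.
    """
    registry = registry if registry is not None else LogTransformRegistry()
    reference = reference or default_reference(exposure)
    y_raw = pd.to_numeric(table[outcome], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(y_raw)
    sub = table.loc[keep]
    y, logged = registry.transform(outcome, y_raw[keep])

    X, terms = trajectory_design(sub, exposure, reference)
    dropped: List[str] = []
    for t in list(terms):
        colvals = X[t].to_numpy()
        if colvals.sum() == 0 or colvals.sum() == len(colvals):
            dropped.append(t)
            terms.remove(t)
            X = X.drop(columns=[t])
    if dropped:
        warnings.warn(
            f"dropped empty/collinear dummy terms for {outcome!r}: {dropped}",
            stacklevel=2,
        )
    fit = sm.OLS(y, X.to_numpy(), hasconst=True).fit()
    names = list(X.columns)
    est = dict(zip(names, fit.params))
    ses = dict(zip(names, fit.bse))
    ps = dict(zip(names, fit.pvalues))
    term_list = [
        TermEstimate(t, float(est[t]), float(ses[t]), float(ps[t]), bool(ps[t] <= alpha))
        for t in terms
    ]
    return ModelResult(
        outcome=outcome,
        exposure=exposure,
        reference=reference.value,
        terms=term_list,
        intercept=float(est["const"]),
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        f_p=float(fit.f_pvalue),
        n=int(fit.nobs),
        log_transformed=logged,
        alpha=alpha,
        dropped=dropped,
    )


@dataclass
class BatteryResult:
    """All ANOVA screens and adjusted models for one analytic table."""

    models: List[ModelResult]
    anovas: List[AnovaResult]
    alpha: float

    def models_frame(self, exposure: Optional[str] = None) -> pd.DataFrame:
        rows = [m.to_row() for m in self.models if exposure in (None, m.exposure)]
        return pd.DataFrame(rows)

    def anova_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "outcome": a.outcome,
                    "exposure": a.exposure,
                    "f_stat": a.f_stat,
                    "p": a.p,
                    "group_count": a.group_count,
                    "n": a.n,
                }
                for a in self.anovas
            ]
        )


def run_battery(
    table: pd.DataFrame,
    outcomes: Optional[Sequence[str]] = None,
    exposures: Sequence[str] = ("poverty", "share"),
    alpha: float = ALPHA_BONFERRONI,
    registry: Optional[LogTransformRegistry] = None,
) -> BatteryResult:
    """Run ANOVA + adjusted model for every exposure x outcome pair.

    The ANOVA screens use the same (possibly log-transformed) outcome scale
    as the adjusted models, so both test the same quantity.
    """
    registry = registry if registry is not None else LogTransformRegistry()
    outcomes = list(outcomes) if outcomes is not None else [
        m for m in OUTCOME_MEASURES if m in table.columns
    ]
    missing = [o for o in outcomes if o not in table.columns]
    if missing:
        raise ValueError(f"outcomes absent from table: {missing}")
    models: List[ModelResult] = []
    anovas: List[AnovaResult] = []
    for exposure in exposures:
        col = f"{exposure}_trajectory"
        for outcome in outcomes:
            y_raw = pd.to_numeric(table[outcome], errors="coerce").to_numpy(dtype=float)
            y_t, _ = registry.transform(outcome, y_raw)
            a = anova_by_trajectory(y_t, table[col].to_numpy())
            anovas.append(
                AnovaResult(outcome, exposure, a.f_stat, a.p, a.group_count, a.n)
            )
            models.append(
                fit_trajectory_model(
                    table, outcome, exposure=exposure, registry=registry, alpha=alpha
                )
            )
    return BatteryResult(models=models, anovas=anovas, alpha=alpha)


def fit_negative_trajectory_logistic(
    table: pd.DataFrame,
    reference: TrajectoryLabel = TrajectoryLabel.LONG_TERM_HIGH,
    adjust_density: bool = False,
) -> OddsRatioResult:
    """Logistic model of the negative-poverty-trajectory indicator.

    The outcome is 1 for tracts long-term high or increasing in poverty;
    predictors are the group-share trajectory dummies (reference:
    long-term-high share).  Wald 95% CIs are reported on the OR scale.
    Perfect separation is reported via ``separation=True`` (with infinite
    or unstable estimates left as fitted) rather than failing silently.
    """
    y = table["poverty_trajectory"].isin(NEGATIVE_POVERTY_LABELS).to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both outcome classes must be present")
    levels = [lab.value for lab in FIVE_LABELS if lab is not reference]
    X = pd.DataFrame(index=table.index)
    X["const"] = 1.0
    for lab in list(levels):
        col = (table["share_trajectory"] == lab).astype(float)
        if col.sum() == 0:  # level absent (e.g. collapsed designs)
            levels.remove(lab)
            continue
        X[lab] = col
    if adjust_density:
        for q in QUARTILE_LEVELS[:-1]:
            X[q] = (table["density_quartile"] == q).astype(float)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=200)
            params = dict(zip(X.columns, fit.params))
            bse = dict(zip(X.columns, fit.bse))
        except Exception:  # pragma: no cover - perfect separation path
            separation = True
            params = {c: np.nan for c in X.columns}
            bse = {c: np.nan for c in X.columns}
    if not separation and any(
        not np.isfinite(bse[l]) or abs(params[l]) > 15 for l in levels
    ):
        separation = True
    ors = {l: float(np.exp(params[l])) for l in levels}
    lo = {l: float(np.exp(params[l] - _Z975 * bse[l])) for l in levels}
    hi = {l: float(np.exp(params[l] + _Z975 * bse[l])) for l in levels}
    return OddsRatioResult(
        reference=reference.value,
        levels=levels,
        odds_ratios=ors,
        ci_lower=lo,
        ci_upper=hi,
        n=int(y.size),
        separation=separation,
    )


def ols_many(X: np.ndarray, Y: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit many OLS models sharing one design matrix.

    ``X`` is (n, k), ``Y`` is (n, m): one column per simulated outcome.
    Returns (betas, ses, pvalues), each (k, m), using classical standard
    errors and two-sided t tests with n - k degrees of freedom.  Used by the
    calibration studies, which refit tens of thousands of outcomes.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ (X.T @ Y)
    resid = Y - X @ betas
    rss = np.sum(resid**2, axis=0)
    sigma2 = rss / (n - k)
    ses = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    tvals = betas / ses
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - k)
    return betas, ses, pvals
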