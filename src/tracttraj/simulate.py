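"""Synthetic census-tract panel, SDOH and health tables.

The generator emulates the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without the source data products
(a commercial tract panel, a federal SDOH compilation, and modeled
small-area health estimates):

* each tract draws a latent 20-year **poverty trajectory class** from a
  five-class mixture (default class probabilities are the published Texas
  shares), and a **group-share class** coupled to it through a
  comonotone-mixture copula, reproducing the strong observed co-occurrence
  of long-term-low poverty with long-term-high White share;
* year-specific composition percentages are drawn *band-consistently*:
  constant classes stay inside one category band for all three years,
  increasing/decreasing classes follow a band-monotone path, so the
  classification stage recovers the planted class exactly;
* controlled numbers of tracts are planted with a missing poverty year or a
  non-classifiable category pattern, to exercise the exclusion ledger;
* the 12 SDOH + 14 health outcomes are linear in trajectory and
  density-quartile dummies with additive Gaussian noise; measures in the
  log-transform registry are generated on the exponentiated scale so the
  pipeline's log transform exactly linearizes them.

Percentage outcomes are clipped to their support only when clipping touches
fewer than 0.1% of values; otherwise generation aborts, because silent
truncation would bias parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .measures import MEASURES, MEASURE_NAMES, get_measure
from .trajectory import (
    FIVE_LABELS,
    PatternRule,
    TrajectoryLabel,
    YEARS,
    undefined_patterns,
)

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "SimulationResult",
    "default_trajectory_probs",
    "default_effect_table",
    "default_noise_sd",
    "default_config",
    "generate_panel",
    "plant_exclusions",
    "generate_outcomes",
    "simulate_dataset",
]

#: Published Texas trajectory shares (percent, as printed; they sum to 100.1
#: due to rounding and are renormalized for use as mixture probabilities).
_POVERTY_SHARES = {
    TrajectoryLabel.LONG_TERM_LOW: 11.4,
    TrajectoryLabel.LONG_TERM_MODERATE: 30.1,
    TrajectoryLabel.LONG_TERM_HIGH: 24.2,
    TrajectoryLabel.INCREASING: 20.7,
    TrajectoryLabel.DECREASING: 13.7,
}
_SHARE_SHARES = {
    TrajectoryLabel.LONG_TERM_LOW: 32.0,
    TrajectoryLabel.LONG_TERM_MODERATE: 20.2,
    TrajectoryLabel.LONG_TERM_HIGH: 19.0,
    TrajectoryLabel.INCREASING: 12.8,
    TrajectoryLabel.DECREASING: 16.1,
}

#: Latent-class orderings used by the copula.  Poverty classes are ordered by
#: increasing disadvantage and group-share classes by decreasing advantage, so
#: a shared latent uniform couples low-poverty histories with high-share ones.
_POVERTY_COPULA_ORDER = (
    TrajectoryLabel.LONG_TERM_LOW,
    TrajectoryLabel.DECREASING,
    TrajectoryLabel.LONG_TERM_MODERATE,
    TrajectoryLabel.INCREASING,
    TrajectoryLabel.LONG_TERM_HIGH,
)
_SHARE_COPULA_ORDER = (
    TrajectoryLabel.LONG_TERM_HIGH,
    TrajectoryLabel.INCREASING,
    TrajectoryLabel.LONG_TERM_MODERATE,
    TrajectoryLabel.DECREASING,
    TrajectoryLabel.LONG_TERM_LOW,
)

_QUARTILES = ("Q1", "Q2", "Q3", "Q4")

# Band triples (as level indices) consistent with each trajectory class under
# the MONOTONE rule (and, being monotone, under ENDPOINT as well).
_INCREASING_TRIPLES: Tuple[Tuple[int, int, int], ...] = (
    (0, 0, 1), (0, 1, 1), (0, 0, 2), (0, 1, 2), (0, 2, 2), (1, 1, 2), (1, 2, 2),
)
_DECREASING_TRIPLES = tuple(t[::-1] for t in _INCREASING_TRIPLES)
_CLASS_TRIPLES: Dict[TrajectoryLabel, Tuple[Tuple[int, int, int], ...]] = {
    TrajectoryLabel.LONG_TERM_LOW: ((0, 0, 0),),
    TrajectoryLabel.LONG_TERM_MODERATE: ((1, 1, 1),),
    TrajectoryLabel.LONG_TERM_HIGH: ((2, 2, 2),),
    TrajectoryLabel.INCREASING: _INCREASING_TRIPLES,
    TrajectoryLabel.DECREASING: _DECREASING_TRIPLES,
}

#: Expected clipped fraction allowed when choosing default noise scales
#: (a tenth of the generator's hard 0.1% guard, leaving sampling headroom).
_CLIP_BUDGET = 1e-4


@dataclass(frozen=True)
class EffectSpec:
    """Additive effects for one outcome, on its modeling scale.

    ``trajectory`` maps the four non-reference poverty-trajectory labels
    (reference: long-term low) to additive effects; ``density`` maps Q1–Q3
    (reference: Q4, the highest-density quartile).
    """

    intercept: float
    trajectory: Mapping[TrajectoryLabel, float]
    density: Mapping[str, float]

    def cell(self, label: TrajectoryLabel, quartile: str) -> float:
        return (
            self.intercept
            + float(self.trajectory.get(label, 0.0))
            + float(self.density.get(quartile, 0.0))
        )


def default_trajectory_probs() -> Dict[str, Dict[TrajectoryLabel, float]]:
    """Mixture probabilities from the published trajectory shares."""
    out = {}
    for key, shares in (("poverty", _POVERTY_SHARES), ("share", _SHARE_SHARES)):
        total = sum(shares.values())
        out[key] = {lab: v / total for lab, v in shares.items()}
    return out


def _transformed(name: str, value: float) -> float:
    m = get_measure(name)
    return math.log(value + m.offset) if m.log else float(value)


def default_effect_table(
    trajectory_probs: Mapping[TrajectoryLabel, float] | None = None,
) -> Dict[str, EffectSpec]:
    """Published contrasts as planted effects, for every outcome.

    The intercept of each outcome is chosen so that the mixture-weighted mean
    of the linear predictor (over trajectory classes at the given
    probabilities and equal-mass density quartiles) equals the published
    statewide median on the modeling scale — keeping simulated levels
    realistic while the contrasts equal the published betas exactly.
    """
    probs = trajectory_probs or default_trajectory_probs()["poverty"]
    non_ref = FIVE_LABELS[1:]  # LTM, LTH, INC, DEC
    table: Dict[str, EffectSpec] = {}
    for m in MEASURES:
        traj = dict(zip(non_ref, m.traj_betas))
        dens = dict(zip(("Q1", "Q2", "Q3"), m.density_betas))
        mean_traj = sum(probs[lab] * beta for lab, beta in traj.items())
        mean_dens = sum(dens.values()) / 4.0
        intercept = _transformed(m.name, m.median) - mean_traj - mean_dens
        spec = EffectSpec(intercept=intercept, trajectory=traj, density=dens)
        intercept += _support_shift(m.name, spec)
        table[m.name] = EffectSpec(intercept=intercept, trajectory=traj, density=dens)
    return table


def _support_shift(name: str, spec: EffectSpec) -> float:
    """Smallest intercept shift keeping every cell mean inside the support.

    The additive contrasts are taken from observed (nonlinear) data, so for a
    few bounded measures the cell means implied by the overall median dip
    just outside the support; the intercept is nudged in by a small margin
    (0.5% of the support width on the modeling scale).
    """
    m = get_measure(name)
    lo, hi = m.support
    lo_t = None if (lo is None or m.log) else lo
    hi_t = None if hi is None else (_transformed(name, hi) if m.log else hi)
    cells = [spec.cell(lab, q) for lab in FIVE_LABELS for q in _QUARTILES]
    if lo_t is not None and hi_t is not None:
        margin = 0.005 * (hi_t - lo_t)
    else:
        margin = 0.05
    shift = 0.0
    if lo_t is not None and min(cells) < lo_t + margin:
        shift = (lo_t + margin) - min(cells)
    if hi_t is not None and max(cells) + shift > hi_t - margin:
        new_shift = (hi_t - margin) - max(cells)
        if lo_t is not None and min(cells) + new_shift < lo_t + margin:
            raise ValueError(
                f"planted effects for {name!r} cannot fit inside its support"
            )
        shift = new_shift
    return shift


def _expected_clip_fraction(
    name: str,
    spec: EffectSpec,
    sd: float,
    probs: Mapping[TrajectoryLabel, float],
) -> float:
    """Expected fraction of draws landing outside the support, by cell."""
    m = get_measure(name)
    lo, hi = m.support
    lo_t = None if (lo is None or m.log) else lo  # exp scale never crosses -offset
    hi_t = None if hi is None else (_transformed(name, hi) if m.log else hi)
    etas = np.array([spec.cell(lab, q) for lab in FIVE_LABELS for q in _QUARTILES])
    w = np.repeat([probs[lab] * 0.25 for lab in FIVE_LABELS], len(_QUARTILES))
    frac = 0.0
    if lo_t is not None:
        frac += float(w @ norm.cdf((lo_t - etas) / sd))
    if hi_t is not None:
        frac += float(w @ norm.cdf((etas - hi_t) / sd))
    return frac


def default_noise_sd(
    effect_table: Mapping[str, EffectSpec] | None = None,
    trajectory_probs: Mapping[TrajectoryLabel, float] | None = None,
    n_reference: int = 2961,
) -> Dict[str, float]:
    """Residual SDs implied by the published standard errors, bound-capped.

    The published SE of the long-term-moderate contrast at N tracts implies a
    residual SD of roughly ``se / sqrt(1/n_LTM + 1/n_LTL)``.  For outcomes
    with hard support bounds the SD is then reduced (by bisection on the
    expected clipped fraction) until clipping stays within the generator's
    guard budget.
    """
    probs = trajectory_probs or default_trajectory_probs()["poverty"]
    table = effect_table or default_effect_table(probs)
    n_ltl = probs[TrajectoryLabel.LONG_TERM_LOW] * n_reference
    n_ltm = probs[TrajectoryLabel.LONG_TERM_MODERATE] * n_reference
    contrast_factor = math.sqrt(1.0 / n_ltm + 1.0 / n_ltl)
    out: Dict[str, float] = {}
    for m in MEASURES:
        implied = m.se / contrast_factor
        spec = table[m.name]
        if _expected_clip_fraction(m.name, spec, implied, probs) <= _CLIP_BUDGET:
            out[m.name] = implied
            continue
        lo_sd, hi_sd = 1e-9, implied
        if _expected_clip_fraction(m.name, spec, lo_sd, probs) > _CLIP_BUDGET:
            raise ValueError(
                f"effect table pushes {m.name!r} outside its support even without noise"
            )
        for _ in range(60):
            mid = 0.5 * (lo_sd + hi_sd)
            if _expected_clip_fraction(m.name, spec, mid, probs) > _CLIP_BUDGET:
                hi_sd = mid
            else:
                lo_sd = mid
        out[m.name] = lo_sd
    return out


@lru_cache(maxsize=1)
def _cached_defaults() -> Tuple[Dict[str, EffectSpec], Dict[str, float]]:
    table = default_effect_table()
    return table, default_noise_sd(table)


@dataclass
class SimulationConfig:
    """Everything the generator needs; fully deterministic given ``seed``."""

    n_tracts: int = 5265
    trajectory_probs: Dict[str, Dict[TrajectoryLabel, float]] = field(
        default_factory=default_trajectory_probs
    )
    cooccurrence_strength: float = 0.55
    effect_table: Dict[str, EffectSpec] = field(
        default_factory=lambda: dict(_cached_defaults()[0])
    )
    noise_sd: Dict[str, float] = field(
        default_factory=lambda: dict(_cached_defaults()[1])
    )
    n_missing: int = 69
    n_nonpattern: int = 29
    seed: int = 0
    poverty_edges: Tuple[float, float] = (5.0, 20.0)
    share_edges: Tuple[float, float] = (100.0 / 3.0, 200.0 / 3.0)
    poverty_cap: float = 60.0  # realistic upper draw limit for the HIGH band
    share_cap: float = 100.0
    n_health_tracts: Optional[int] = 2961
    density_log_mean: float = math.log(1000.0)
    density_log_sd: float = 1.0

    def validate(self) -> None:
        if self.n_tracts <= 0:
            raise ValueError("n_tracts must be positive")
        if self.n_missing < 0 or self.n_nonpattern < 0:
            raise ValueError("exclusion counts must be non-negative")
        if self.n_missing + self.n_nonpattern > self.n_tracts:
            raise ValueError("n_missing + n_nonpattern exceeds n_tracts")
        if not (0.0 <= self.cooccurrence_strength <= 1.0):
            raise ValueError("cooccurrence_strength must be in [0, 1]")
        for key in ("poverty", "share"):
            probs = self.trajectory_probs[key]
            if set(probs) != set(FIVE_LABELS):
                raise ValueError(f"trajectory_probs[{key!r}] must cover the five labels")
            if any(p < 0.0 or p > 1.0 for p in probs.values()):
                raise ValueError("probabilities must lie in [0, 1]")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"trajectory_probs[{key!r}] must sum to 1 within 1e-9")
        unknown = set(self.effect_table) - set(MEASURE_NAMES)
        if unknown:
            raise ValueError(
                f"unknown outcome name(s) in effect_table: {sorted(unknown)}; "
                f"valid names: {', '.join(MEASURE_NAMES)}"
            )
        for name in self.effect_table:
            sd = self.noise_sd.get(name)
            if sd is None or sd < 0.0:
                raise ValueError(f"noise_sd for {name!r} must be present and >= 0")


def default_config(**overrides) -> SimulationConfig:
    """The default study scenario (5265 tracts, 69 + 29 exclusions)."""
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class SimulationResult:
    """All generator outputs for one run."""

    panel: pd.DataFrame
    latent: pd.DataFrame
    planted: pd.DataFrame
    sdoh: pd.DataFrame
    health: pd.DataFrame


def _band_bounds(edges: Tuple[float, float], cap: float) -> Tuple[Tuple[float, float], ...]:
    e1, e2 = edges
    return ((0.0, e1), (e1, e2), (e2, cap))


def _draw_in_band(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    # open at the lower edge so MODERATE/HIGH draws never fall on the boundary
    u = rng.uniform(0.0, 1.0, size=n)
    vals = lo + (hi - lo) * u
    return np.maximum(vals, np.nextafter(lo, hi))


def _sample_paths(
    rng: np.random.Generator,
    classes: np.ndarray,
    edges: Tuple[float, float],
    cap: float,
) -> np.ndarray:
    """Band-consistent three-year values for each tract's latent class."""
    bounds = _band_bounds(edges, cap)
    n = classes.shape[0]
    values = np.empty((n, 3), dtype=float)
    for lab in FIVE_LABELS:
        idx = np.flatnonzero(classes == lab.value)
        if idx.size == 0:
            continue
        triples = _CLASS_TRIPLES[lab]
        choice = rng.integers(0, len(triples), size=idx.size)
        for t_i, triple in enumerate(triples):
            sub = idx[choice == t_i]
            if sub.size == 0:
                continue
            for year_pos, band in enumerate(triple):
                lo, hi = bounds[band]
                values[sub, year_pos] = _draw_in_band(rng, lo, hi, sub.size)
    return values


def _inverse_cdf_classes(
    u: np.ndarray, probs: Mapping[TrajectoryLabel, float], order: Sequence[TrajectoryLabel]
) -> np.ndarray:
    cum = np.cumsum([probs[lab] for lab in order])
    cum[-1] = 1.0 + 1e-12
    idx = np.searchsorted(cum, u, side="left")
    labels = np.array([lab.value for lab in order], dtype=object)
    return labels[idx]


def generate_panel(config: SimulationConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the tract composition panel and its latent trajectory classes.

    Returns ``(panel, latent)``: the panel holds tract_id, the three poverty
    and three group-share percentages and 2010 population density; the latent
    frame records each tract's true poverty and share classes for recovery
    tests.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_tracts
    tract_ids = np.array([f"48{i:09d}" for i in range(n)], dtype=object)

    u_pov = rng.uniform(size=n)
    shared = rng.uniform(size=n) < config.cooccurrence_strength
    u_share = np.where(shared, u_pov, rng.uniform(size=n))
    pov_class = _inverse_cdf_classes(
        u_pov, config.trajectory_probs["poverty"], _POVERTY_COPULA_ORDER
    )
    share_class = _inverse_cdf_classes(
        u_share, config.trajectory_probs["share"], _SHARE_COPULA_ORDER
    )

    pov_vals = _sample_paths(rng, pov_class, config.poverty_edges, config.poverty_cap)
    share_vals = _sample_paths(rng, share_class, config.share_edges, config.share_cap)
    density = rng.lognormal(config.density_log_mean, config.density_log_sd, size=n)

    panel = pd.DataFrame({"tract_id": tract_ids})
    for j, y in enumerate(YEARS):
        panel[f"pov_{y}"] = pov_vals[:, j]
    for j, y in enumerate(YEARS):
        panel[f"share_{y}"] = share_vals[:, j]
    panel["density_2010"] = density

    latent = pd.DataFrame(
        {"tract_id": tract_ids, "poverty_class": pov_class, "share_class": share_class}
    )
    return panel, latent


def plant_exclusions(
    panel: pd.DataFrame,
    config: SimulationConfig,
    rule: PatternRule = PatternRule.MONOTONE,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Plant missing poverty years and non-classifiable poverty patterns.

    Exactly ``config.n_missing`` tracts get one poverty year blanked and
    exactly ``config.n_nonpattern`` *other* tracts get their poverty triple
    overwritten with a band pattern the active rule maps to UNDEFINED.
    Returns the modified panel and a frame of planted tract ids with the
    planted kind.  Deterministic given ``config.seed``.
    """
    config.validate()
    if config.n_missing + config.n_nonpattern > len(panel):
        raise ValueError("cannot plant more exclusions than tracts")
    panel = panel.copy()
    rng = np.random.default_rng([config.seed, 1])
    picks = rng.choice(len(panel), size=config.n_missing + config.n_nonpattern, replace=False)
    miss_idx = picks[: config.n_missing]
    pat_idx = picks[config.n_missing:]

    pov_cols = [f"pov_{y}" for y in YEARS]
    if config.n_missing:
        which_year = rng.integers(0, 3, size=miss_idx.size)
        for row, yj in zip(miss_idx, which_year):
            panel.iloc[row, panel.columns.get_loc(pov_cols[yj])] = np.nan

    if config.n_nonpattern:
        candidates = undefined_patterns(rule)
        if not candidates:
            raise ValueError(f"rule {rule!r} admits no undefined pattern; cannot plant")
        triple = candidates[0]  # e.g. (LOW, HIGH, LOW) under either rule
        bounds = _band_bounds(config.poverty_edges, config.poverty_cap)
        for yj, cat in enumerate(triple):
            lo, hi = bounds[int(cat)]
            draws = _draw_in_band(rng, lo, hi, pat_idx.size)
            panel.iloc[pat_idx, panel.columns.get_loc(pov_cols[yj])] = draws

    planted = pd.DataFrame(
        {
            "tract_id": np.concatenate(
                [
                    panel["tract_id"].to_numpy()[miss_idx],
                    panel["tract_id"].to_numpy()[pat_idx],
                ]
            ),
            "kind": ["missing_data"] * miss_idx.size + ["undefined_pattern"] * pat_idx.size,
        }
    )
    return panel, planted


def _density_quartiles(density: np.ndarray) -> np.ndarray:
    # local copy of the linkage convention to avoid a circular import;
    # covered by a cross-module consistency test
    cuts = np.percentile(density, [25.0, 50.0, 75.0])
    idx = np.searchsorted(cuts, density, side="left")
    return np.array(_QUARTILES, dtype=object)[idx]


def generate_outcomes(
    panel: pd.DataFrame,
    latent: pd.DataFrame,
    config: SimulationConfig,
    exclude_ids: Optional[Iterable[str]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the SDOH and health tables from planted effects.

    Each outcome is ``intercept + trajectory effect + density-quartile effect
    + Gaussian noise`` on its modeling scale; log-registry outcomes are then
    exponentiated (minus their offset).  The health table is restricted to
    the ``config.n_health_tracts`` densest tracts outside ``exclude_ids``,
    emulating modeled health estimates being available only for urbanized
    tracts.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    merged = panel.merge(latent, on="tract_id", validate="one_to_one")
    n = len(merged)
    quart = _density_quartiles(merged["density_2010"].to_numpy(dtype=float))
    labels = merged["poverty_class"].to_numpy()

    data: Dict[str, np.ndarray] = {}
    for name, spec in config.effect_table.items():
        m = get_measure(name)
        eta = np.full(n, spec.intercept, dtype=float)
        for lab, beta in spec.trajectory.items():
            eta[labels == TrajectoryLabel(lab).value] += float(beta)
        for q, beta in spec.density.items():
            eta[quart == q] += float(beta)
        sd = config.noise_sd[name]
        eps = rng.normal(0.0, sd, size=n)
        x = eta + eps
        vals = np.exp(x) - m.offset if m.log else x
        lo, hi = m.support
        lo_eff = None if m.log else lo  # exponentiated draws respect the lower bound
        hi_t = None if hi is None else (_transformed(name, hi) if m.log else hi)
        # guard on the *expected* clipped fraction implied by the config, so
        # the abort decision is a property of noise_sd, not of one draw
        if sd > 0:
            expected = 0.0
            if lo_eff is not None:
                expected += float(np.mean(norm.cdf((lo_eff - eta) / sd)))
            if hi_t is not None:
                expected += float(np.mean(norm.cdf((eta - hi_t) / sd)))
            if expected >= 1e-3:
                raise ValueError(
                    f"noise_sd for {name!r} clips an expected "
                    f"{expected:.2%} of values (>= 0.1%); reduce the noise "
                    "or the effects"
                )
        if lo_eff is not None:
            vals = np.maximum(vals, lo_eff)
        if hi is not None:
            vals = np.minimum(vals, hi)
        data[name] = vals

    sdoh_cols = [m.name for m in MEASURES if m.group == "sdoh" and m.name in data]
    health_cols = [m.name for m in MEASURES if m.group != "sdoh" and m.name in data]
    sdoh = pd.DataFrame({"tract_id": merged["tract_id"], **{c: data[c] for c in sdoh_cols}})
    health = pd.DataFrame(
        {"tract_id": merged["tract_id"], **{c: data[c] for c in health_cols}}
    )

    if config.n_health_tracts is not None and config.n_health_tracts < n:
        excluded = set(exclude_ids) if exclude_ids is not None else set()
        eligible = merged[~merged["tract_id"].isin(excluded)]
        if config.n_health_tracts > len(eligible):
            raise ValueError("n_health_tracts exceeds the number of eligible tracts")
        keep = eligible.nlargest(config.n_health_tracts, "density_2010")["tract_id"]
        health = health[health["tract_id"].isin(set(keep))].reset_index(drop=True)
    return sdoh, health


def simulate_dataset(
    config: SimulationConfig | None = None,
    rule: PatternRule = PatternRule.MONOTONE,
) -> SimulationResult:
    """Run the full generator: panel, planted exclusions, outcome tables."""
    config = config or default_config()
    panel, latent = generate_panel(config)
    panel, planted = plant_exclusions(panel, config, rule)
    sdoh, health = generate_outcomes(
        panel, latent, config, exclude_ids=planted["tract_id"]
    )
    return SimulationResult(panel=panel, latent=latent, planted=planted, sdoh=sdoh, health=health)
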