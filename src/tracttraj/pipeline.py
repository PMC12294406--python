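"""End-to-end orchestration: simulate -> classify -> link -> analyze.

``run_pipeline`` executes the full analysis on either a simulated dataset or
three user-supplied CSV tables, writing an auditable set of artifacts to the
output directory.  Reruns with the same configuration and seed are
byte-identical (no timestamps; fixed CSV float formatting).

Artifacts written (exactly these ten files):

========================  ====================================================
``config.yaml``           verbatim echo of the resolved configuration
``run_log.json``          seed, package/library versions, stage counts
``assignments.csv``       per-tract categories, labels, exclusion reasons
``ledger.csv``            ordered exclusion ledger across all stages
``analytic_table.csv``    merged tract x measure table with factors
``summary.csv``           medians/ranges and trajectory percent distributions
``models_poverty.csv``    adjusted linear models, poverty exposure
``models_share.csv``      adjusted linear models, group-share exposure
``anova.csv``             one-way ANOVA screens for both exposures
``logistic.csv``          negative-poverty-trajectory odds ratios
========================  ====================================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import scipy
import statsmodels
import yaml

from . import __version__
from .association import (
    ALPHA_BONFERRONI,
    LogTransformRegistry,
    fit_negative_trajectory_logistic,
    run_battery,
    summarize,
)
from .linkage import build_analytic_table
from .simulate import SimulationConfig, default_config, simulate_dataset
from .trajectory import (
    CategorizationScheme,
    ExclusionLedger,
    PatternRule,
    classify_panel,
)

__all__ = ["PipelineConfig", "ARTIFACTS", "default_study_config", "run_pipeline", "read_table"]

ARTIFACTS = (
    "config.yaml",
    "run_log.json",
    "assignments.csv",
    "ledger.csv",
    "analytic_table.csv",
    "summary.csv",
    "models_poverty.csv",
    "models_share.csv",
    "anova.csv",
    "logistic.csv",
)

_FLOAT_FMT = "%.10g"


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV, keeping tract identifiers as text."""
    return pd.read_csv(path, dtype={"tract_id": str})


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass
class PipelineConfig:
    """One reproducible run: data source, classification choices, alpha."""

    seed: int = 0
    out_dir: str = "tracttraj_out"
    simulate: Optional[Dict] = field(default_factory=dict)  # SimulationConfig overrides
    inputs: Optional[Dict[str, str]] = None  # {"panel": ..., "sdoh": ..., "health": ...}
    poverty_scheme: CategorizationScheme = field(default_factory=CategorizationScheme)
    share_scheme: CategorizationScheme = field(
        default_factory=lambda: CategorizationScheme(edges=(100.0 / 3.0, 200.0 / 3.0))
    )
    rule: PatternRule = PatternRule.MONOTONE
    alpha: float = ALPHA_BONFERRONI
    log_offsets: Optional[Dict[str, float]] = None  # None -> default registry
    adjust_density_logistic: bool = False

    def registry(self) -> LogTransformRegistry:
        if self.log_offsets is None:
            return LogTransformRegistry()
        return LogTransformRegistry(dict(self.log_offsets))

    def to_dict(self) -> Dict:
        d = {
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "simulate": dict(self.simulate) if self.simulate is not None else None,
            "inputs": dict(self.inputs) if self.inputs else None,
            "poverty_scheme": {
                "mode": self.poverty_scheme.mode,
                "edges": list(self.poverty_scheme.edges),
                "tertile_scope": self.poverty_scheme.tertile_scope,
            },
            "share_scheme": {
                "mode": self.share_scheme.mode,
                "edges": list(self.share_scheme.edges),
                "tertile_scope": self.share_scheme.tertile_scope,
            },
            "rule": self.rule.value,
            "alpha": self.alpha,
            "log_offsets": dict(self.log_offsets) if self.log_offsets else None,
            "adjust_density_logistic": self.adjust_density_logistic,
        }
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        def scheme(key: str, default: CategorizationScheme) -> CategorizationScheme:
            s = d.get(key)
            if not s:
                return default
            return CategorizationScheme(
                mode=s.get("mode", "fixed"),
                edges=tuple(s.get("edges", (5.0, 20.0))),
                tertile_scope=s.get("tertile_scope", "per_year"),
            )

        return cls(
            seed=int(d.get("seed", 0)),
            out_dir=d.get("out_dir", "tracttraj_out"),
            simulate=d.get("simulate", {}) if d.get("inputs") is None else None,
            inputs=d.get("inputs"),
            poverty_scheme=scheme("poverty_scheme", CategorizationScheme()),
            share_scheme=scheme(
                "share_scheme", CategorizationScheme(edges=(100.0 / 3.0, 200.0 / 3.0))
            ),
            rule=PatternRule(d.get("rule", "monotone")),
            alpha=float(d.get("alpha", ALPHA_BONFERRONI)),
            log_offsets=d.get("log_offsets"),
            adjust_density_logistic=bool(d.get("adjust_density_logistic", False)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_study_config(seed: int = 0, out_dir: str = "tracttraj_out") -> PipelineConfig:
    """The default scenario: 5265 tracts, 69 + 29 planted exclusions, 2961
    health-covered tracts, published trajectory shares and effects."""
    return PipelineConfig(seed=seed, out_dir=out_dir, simulate={})


def _simulation_config(cfg: PipelineConfig) -> SimulationConfig:
    overrides = dict(cfg.simulate or {})
    overrides.setdefault("seed", cfg.seed)
    return default_config(**overrides)


def _load_inputs(cfg: PipelineConfig) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    paths = cfg.inputs or {}
    for key in ("panel", "sdoh", "health"):
        if key not in paths:
            raise ValueError(f"inputs must provide a {key!r} path")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(paths[key])
    return (
        read_table(paths["panel"]),
        read_table(paths["sdoh"]),
        read_table(paths["health"]),
    )


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Any stage failure propagates with the stage name prefixed.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "simulate/load"
    try:
        if cfg.inputs:
            panel, sdoh, health = _load_inputs(cfg)
            mode = "loaded"
        else:
            sim = simulate_dataset(_simulation_config(cfg), rule=cfg.rule)
            panel, sdoh, health = sim.panel, sim.sdoh, sim.health
            mode = "simulated"

        stage = "classify"
        pov_assign, pov_ledger = classify_panel(
            panel, "poverty", cfg.poverty_scheme, cfg.rule
        )
        share_assign, share_ledger = classify_panel(
            panel, "share", cfg.share_scheme, cfg.rule
        )

        stage = "link"
        table, link_ledger = build_analytic_table(
            panel, pov_assign, share_assign, sdoh, health
        )
        ledger = ExclusionLedger(
            entries=pov_ledger.entries + share_ledger.entries + link_ledger.entries
        )

        stage = "analyze"
        registry = cfg.registry()
        summary = summarize(table)
        battery = run_battery(table, alpha=cfg.alpha, registry=registry)
        logistic = fit_negative_trajectory_logistic(
            table, adjust_density=cfg.adjust_density_logistic
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    assignments = pov_assign.rename(
        columns={
            "cat_1990": "pov_cat_1990",
            "cat_2000": "pov_cat_2000",
            "cat_2010": "pov_cat_2010",
            "trajectory": "poverty_trajectory",
            "exclusion_reason": "poverty_exclusion",
        }
    ).merge(
        share_assign.rename(
            columns={
                "cat_1990": "share_cat_1990",
                "cat_2000": "share_cat_2000",
                "cat_2010": "share_cat_2010",
                "trajectory": "share_trajectory",
                "exclusion_reason": "share_exclusion",
            }
        ),
        on="tract_id",
    )

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    _write_csv(assignments, out / "assignments.csv")
    _write_csv(ledger.to_frame(), out / "ledger.csv")
    _write_csv(table, out / "analytic_table.csv")
    _write_csv(summary, out / "summary.csv")
    _write_csv(battery.models_frame("poverty"), out / "models_poverty.csv")
    _write_csv(battery.models_frame("share"), out / "models_share.csv")
    _write_csv(battery.anova_frame(), out / "anova.csv")
    _write_csv(logistic.to_frame(), out / "logistic.csv")

    log = {
        "tracttraj_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "scipy_version": scipy.__version__,
        "statsmodels_version": statsmodels.__version__,
        "seed": cfg.seed,
        "mode": mode,
        "n_panel_tracts": int(len(panel)),
        "n_classified_poverty": int((pov_assign["trajectory"] != "").sum()),
        "n_classified_share": int((share_assign["trajectory"] != "").sum()),
        "n_analytic_tracts": int(len(table)),
        "ledger": [list(e) for e in ledger.entries],
        "alpha": cfg.alpha,
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
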