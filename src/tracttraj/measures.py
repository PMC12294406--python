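"""Canonical registry of the tract-level measures carried through the pipeline.

Three measure families are analyzed, all ecological (census-tract level):

* **SDOH** — 12 social determinants of health from a 2010 tract-level
  compilation (healthcare distances, housing, socioeconomic and household
  composition measures).
* **HRPB** — 7 modeled health risk / preventive behavior prevalences
  (small-area estimates for adults, 2017 release).
* **HSO** — 7 modeled health status / outcome prevalences from the same
  source.

Each :class:`MeasureSpec` also records the published reference statistics
used as *simulation defaults*: the statewide median and range, the adjusted
linear-model contrasts of each poverty-trajectory category against
long-term-low tracts, the population-density quartile contrasts against the
highest-density quartile, and the standard error of the long-term-moderate
contrast (from which a realistic residual scale is implied).  Six skewed
measures are log-transformed before modeling; their contrasts are on the
log scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "MeasureSpec",
    "MEASURES",
    "MEASURE_NAMES",
    "SDOH_MEASURES",
    "HRPB_MEASURES",
    "HSO_MEASURES",
    "OUTCOME_MEASURES",
    "LOG_MEASURES",
    "DEFAULT_LOG_OFFSETS",
    "get_measure",
]


@dataclass(frozen=True)
class MeasureSpec:
    """One tract-level measure and its published reference statistics.

    Attributes
    ----------
    name:
        Canonical column name used in every table the package reads/writes.
    group:
        Measure family: ``"sdoh"``, ``"hrpb"`` or ``"hso"``.
    label:
        Human-readable label (units in parentheses).
    median, low, high:
        Published statewide median and observed range, on the natural scale.
    log:
        Whether the measure is log-transformed before modeling.
    offset:
        Constant added before taking logs (0 for strictly positive measures,
        1 for percentages that contain zeros).
    support:
        Hard bounds of the natural scale, ``None`` meaning unbounded. Used by
        the simulator's clipping guard.
    traj_betas:
        Adjusted contrasts (long-term moderate, long-term high, increasing,
        decreasing) vs. long-term-low poverty tracts, on the modeling scale.
    density_betas:
        Adjusted contrasts (Q1, Q2, Q3) vs. the highest-density quartile Q4.
    se:
        Standard error of the long-term-moderate contrast, modeling scale.
    """

    name: str
    group: str
    label: str
    median: float
    low: float
    high: float
    log: bool
    offset: float
    support: Tuple[Optional[float], Optional[float]]
    traj_betas: Tuple[float, float, float, float]
    density_betas: Tuple[float, float, float]
    se: float


_PCT = (0.0, 100.0)

MEASURES: Tuple[MeasureSpec, ...] = (
    # ---- social determinants of health (2010) --------------------------
    MeasureSpec("dist_ed", "sdoh", "Distance to nearest emergency department (miles)",
                4.6, 0.1, 51.6, True, 0.0, (0.0, None),
                (0.423, 0.317, 0.282, 0.351), (1.069, 0.463, 0.132), 0.053),
    MeasureSpec("dist_ob", "sdoh", "Distance to nearest obstetrics department (miles)",
                3.2, 0.0, 45.6, True, 0.0, (0.0, None),
                (-0.002, -0.144, -0.006, 0.005), (1.054, 0.209, 0.030), 0.049),
    MeasureSpec("home_value", "sdoh", "Median home value ($)",
                113500.0, 9999.0, 1000001.0, True, 0.0, (0.0, None),
                (-0.489, -1.010, -0.555, -0.524), (-0.190, -0.066, -0.007), 0.038),
    MeasureSpec("renter_occupied", "sdoh", "Renter-occupied housing units (%)",
                32.5, 0.0, 100.0, False, 0.0, _PCT,
                (15.197, 27.306, 20.309, 12.679), (-24.102, -11.294, -8.969), 1.791),
    MeasureSpec("crowded_housing", "sdoh", "Crowded housing (%)",
                3.6, 0.0, 39.8, True, 1.0, _PCT,
                (1.039, 1.852, 1.229, 0.992), (-0.462, -0.353, -0.333), 0.082),
    MeasureSpec("gini", "sdoh", "Gini index of income inequality",
                0.4, 0.0, 0.7, False, 0.0, (0.0, 1.0),
                (0.032, 0.077, 0.041, 0.032), (0.012, -0.003, -0.003), 0.006),
    MeasureSpec("less_than_hs", "sdoh", "Less than high school (%)",
                17.8, 0.0, 100.0, False, 0.0, _PCT,
                (12.390, 33.433, 15.462, 15.045), (-5.220, -4.599, -4.538), 1.149),
    MeasureSpec("bachelors", "sdoh", "Bachelor's degree (%)",
                13.8, 0.0, 61.4, False, 0.0, _PCT,
                (-15.599, -24.425, -15.829, -14.453), (-2.777, -0.237, 0.863), 0.799),
    MeasureSpec("public_assistance", "sdoh", "Public assistance income or SNAP (%)",
                8.5, 0.0, 64.8, True, 1.0, _PCT,
                (1.275, 2.326, 1.453, 1.196), (-0.036, -0.083, -0.131), 0.069),
    MeasureSpec("unemployed", "sdoh", "Unemployed (%)",
                6.5, 0.0, 59.7, False, 0.0, _PCT,
                (2.195, 5.610, 3.295, 2.130), (-1.061, 0.234, 0.141), 0.365),
    MeasureSpec("limited_english", "sdoh", "Limited English proficiency (%)",
                5.8, 0.0, 100.0, True, 1.0, _PCT,
                (0.698, 1.621, 0.997, 0.741), (-1.135, -0.605, -0.466), 0.086),
    MeasureSpec("single_parent", "sdoh", "Single-parent households (%)",
                29.4, 0.0, 100.0, False, 0.0, _PCT,
                (14.176, 26.667, 17.639, 10.779), (-8.667, -1.072, -1.644), 1.396),
    # ---- health risk and preventive behaviors (2017) -------------------
    MeasureSpec("insufficient_sleep", "hrpb", "Insufficient sleep (%)",
                34.8, 21.7, 49.0, False, 0.0, _PCT,
                (0.752, 0.743, 0.617, 0.234), (1.982, 1.601, 0.930), 0.287),
    MeasureSpec("smoking", "hrpb", "Current smoking (%)",
                16.6, 4.5, 40.6, False, 0.0, _PCT,
                (0.469, 0.378, 0.446, 0.210), (1.584, 1.173, 0.409), 0.311),
    MeasureSpec("no_physical_activity", "hrpb", "No physical activity (%)",
                30.4, 13.6, 52.2, False, 0.0, _PCT,
                (2.080, 1.631, 1.916, 1.695), (2.934, 3.141, 1.798), 0.526),
    MeasureSpec("hypertension", "hrpb", "Hypertension (%)",
                29.7, 7.7, 62.9, False, 0.0, _PCT,
                (2.039, 2.062, 1.941, 1.101), (2.911, 2.290, 1.121), 0.432),
    MeasureSpec("dental_visit", "hrpb", "Dental visit (%)",
                57.0, 23.9, 85.5, False, 0.0, _PCT,
                (-2.232, -0.878, -2.308, -1.387), (-2.967, -3.409, -1.710), 0.863),
    MeasureSpec("routine_checkup", "hrpb", "Routine checkup (%)",
                66.5, 50.8, 86.9, False, 0.0, _PCT,
                (0.500, 0.957, 0.276, 0.118), (1.013, 0.253, 0.173), 0.251),
    MeasureSpec("uninsured", "hrpb", "Uninsured (%)",
                25.5, 5.8, 64.1, False, 0.0, _PCT,
                (2.575, 0.974, 2.731, 2.536), (2.460, 3.659, 2.276), 0.841),
    # ---- health status / outcomes (2017) -------------------------------
    MeasureSpec("cancer", "hso", "Cancer (%)",
                4.8, 0.7, 20.9, False, 0.0, _PCT,
                (0.272, 0.354, 0.245, 0.167), (0.245, 0.084, -0.027), 0.103),
    MeasureSpec("copd", "hso", "Chronic obstructive pulmonary disease (%)",
                5.5, 1.3, 18.2, False, 0.0, _PCT,
                (0.551, 0.429, 0.477, 0.325), (0.695, 0.613, 0.280), 0.125),
    MeasureSpec("heart_disease", "hso", "Coronary heart disease (%)",
                5.4, 0.4, 20.9, False, 0.0, _PCT,
                (0.757, 0.619, 0.671, 0.516), (0.637, 0.696, 0.360), 0.131),
    MeasureSpec("diabetes", "hso", "Diabetes (%)",
                10.6, 1.2, 29.4, False, 0.0, _PCT,
                (1.433, 1.280, 1.353, 0.924), (1.234, 1.515, 0.868), 0.280),
    MeasureSpec("obesity", "hso", "Obesity (%)",
                33.1, 15.8, 52.3, False, 0.0, _PCT,
                (1.440, 1.218, 1.346, 1.227), (2.955, 2.646, 1.440), 0.407),
    MeasureSpec("poor_mental_health", "hso", "Poor mental health status (%)",
                11.7, 4.8, 21.8, False, 0.0, _PCT,
                (0.481, 0.169, 0.452, 0.379), (0.657, 0.732, 0.446), 0.191),
    MeasureSpec("poor_physical_health", "hso", "Poor physical health status (%)",
                12.1, 4.0, 30.2, False, 0.0, _PCT,
                (1.325, 0.868, 1.202, 1.015), (1.274, 1.553, 0.883), 0.282),
)

MEASURE_NAMES: Tuple[str, ...] = tuple(m.name for m in MEASURES)
SDOH_MEASURES: Tuple[str, ...] = tuple(m.name for m in MEASURES if m.group == "sdoh")
HRPB_MEASURES: Tuple[str, ...] = tuple(m.name for m in MEASURES if m.group == "hrpb")
HSO_MEASURES: Tuple[str, ...] = tuple(m.name for m in MEASURES if m.group == "hso")
#: The 26 dependent variables of the association battery.
OUTCOME_MEASURES: Tuple[str, ...] = MEASURE_NAMES

#: Measures log-transformed before modeling (skewed distributions).
LOG_MEASURES: Tuple[str, ...] = tuple(m.name for m in MEASURES if m.log)
#: Default log offsets keyed by measure name.
DEFAULT_LOG_OFFSETS = {m.name: m.offset for m in MEASURES if m.log}

_BY_NAME = {m.name: m for m in MEASURES}


def get_measure(name: str) -> MeasureSpec:
    """Look up a measure by canonical name, raising a helpful error."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown measure {name!r}; valid names: {', '.join(MEASURE_NAMES)}"
        ) from None
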