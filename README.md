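# tracttraj

Longitudinal neighborhood trajectories linked to tract-level health.

Most neighborhood–health studies measure context at one point in time.
`tracttraj` implements the longitudinal alternative: classify each census
tract's 20-year (1990→2000→2010) poverty and White-share histories into five
a-priori **trajectories** — long-term low, long-term moderate, long-term
high, increasing, decreasing — link them to tract-level social determinants
of health (SDOH) and modeled health prevalences, and estimate how the
trajectories relate to 26 outcomes.  It is aimed at social epidemiologists
and health-equity researchers who want an auditable, reproducible version of
this design, plus a synthetic-data generator for testing it end to end.

## The model

Each composition value is cut into ordered levels (poverty: 0–5%, 5–20%,
>20%; group share: tertiles), and the level triple maps to a trajectory
label or an undefined sink.  For each outcome *y* and exposure the package
fits

```
g(y_i) = β0 + Σ_t β_t · 1[trajectory_i = t] + Σ_q γ_q · 1[density quartile_i = q] + ε_i
```

with reference categories long-term low (poverty models), long-term high
(share models) and Q4 (highest density quartile); *g* is the natural log for
six right-skewed measures and the identity otherwise.  Terms are flagged at
the family-wise threshold p ≤ 0.001.  An ancillary logistic model estimates
the odds of a *negative poverty trajectory* (long-term high or increasing)
across share trajectories, with Wald 95% CIs.  See `docs/methods.md` for
assumptions, conventions and the generator's design.

## Worked example

```python
import tracttraj as tt
from tracttraj.trajectory import CategorizationScheme, classify_panel

cfg = tt.default_config(n_tracts=3000, n_missing=0, n_nonpattern=0,
                        n_health_tracts=None, seed=3)
sim = tt.simulate_dataset(cfg)
pov, _ = classify_panel(sim.panel, "poverty")
share, _ = classify_panel(sim.panel, "share",
                          CategorizationScheme(edges=(100/3, 200/3)))
table, _ = tt.build_analytic_table(sim.panel, pov, share, sim.sdoh, sim.health)

battery = tt.run_battery(table)
model = next(m for m in battery.models
             if m.outcome == "hypertension" and m.exposure == "poverty")
for t in model.terms:
    print(f"{t.term:<20} beta {t.beta:>7.3f} (se {t.se:.3f}){' *' if t.significant else ''}")
```

prints (seed 3):

```
long_term_moderate   beta   1.913 (se 0.418) *
long_term_high       beta   1.976 (se 0.431) *
increasing           beta   1.800 (se 0.443) *
decreasing           beta   1.318 (se 0.483)
Q1                   beta   2.706 (se 0.351) *
Q2                   beta   2.097 (se 0.351) *
Q3                   beta   0.673 (se 0.351)
```

The generator planted ≈2-percentage-point hypertension contrasts for every
non-reference poverty trajectory; the fitted betas recover them within
sampling error, and the starred terms clear the p ≤ 0.001 threshold.  The
`examples/` directory has one short script per capability (simulation,
classification, linkage/summary, the regression battery, the logistic
model).

## Command line

A thin CLI wraps the same functions:

```
tracttraj simulate --seed 1 --out tables/
tracttraj classify --panel tables/panel.csv --variable poverty --out pov.csv
tracttraj repro    --seed 1 --out run/        # full pipeline, one command
```

`repro` writes ten artifacts (config echo, run log, assignments, exclusion
ledger, analytic table, summary, model tables for both exposures, ANOVA
screens, logistic odds ratios); reruns with the same seed are
byte-identical.

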