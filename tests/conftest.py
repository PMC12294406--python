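import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

from tracttraj import (  # noqa: E402
    build_analytic_table,
    classify_panel,
    default_config,
    simulate_dataset,
)
from tracttraj.trajectory import CategorizationScheme  # noqa: E402

SHARE_SCHEME = CategorizationScheme(edges=(100.0 / 3.0, 200.0 / 3.0))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: 1200 tracts, 8 + 5 planted exclusions, 900
    health-covered tracts."""
    return default_config(
        n_tracts=1200, n_missing=8, n_nonpattern=5, n_health_tracts=900, seed=42
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def analytic(small_sim):
    """Analytic table + full-chain ledger for the scaled-down study."""
    pov, _ = classify_panel(small_sim.panel, "poverty")
    share, _ = classify_panel(small_sim.panel, "share", SHARE_SCHEME)
    table, ledger = build_analytic_table(
        small_sim.panel, pov, share, small_sim.sdoh, small_sim.health
    )
    return table, ledger
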