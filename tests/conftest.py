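import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import lagcast as lc
from lagcast.generator import default_spearman_targets

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_panel():
    """3-jurisdiction panel, 2007-2014, default study conditions."""
    cfg = lc.GeneratorConfig(n_jurisdictions=3, end_month="2014-12", master_seed=123)
    return lc.generate_panel(cfg)


@pytest.fixture(scope="session")
def informative_panel():
    """2-jurisdiction panel with strongly informative proxies."""
    targets = default_spearman_targets()
    targets[0, 1:] = 0.4
    targets[1:, 0] = 0.4
    cfg = lc.GeneratorConfig(
        n_jurisdictions=2, end_month="2013-12", spearman_targets=targets, master_seed=42
    )
    return lc.generate_panel(cfg)


@pytest.fixture(scope="session")
def small_backtest(small_panel):
    """Backtest over 4 cycles, 2 jurisdictions, 3 families (shared)."""
    specs = [lc.ModelSpec(family=f, n_paths=300) for f in ("baseline", "auto", "calls")]
    return lc.run_rolling(
        small_panel,
        "2012-01",
        "2012-04",
        specs,
        master_seed=7,
        jurisdictions=["S01", "S02"],
    )
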