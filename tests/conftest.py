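import numpy as np
import pytest

from esal import (
    RunConfig,
    SyntheticConfig,
    generate_daily_conditions,
    generate_panel,
)


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def panel_and_truth(default_config):
    return generate_panel(default_config)


@pytest.fixture(scope="session")
def daily(default_config):
    return generate_daily_conditions(default_config)


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(baseline_year=1988)


def brute_force_pearson(x, y) -> float:
    """Sum-of-products Pearson formula, independent of scipy/pandas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    num = n * np.sum(x * y) - x.sum() * y.sum()
    den = np.sqrt(n * np.sum(x * x) - x.sum() ** 2) * np.sqrt(
        n * np.sum(y * y) - y.sum() ** 2
    )
    return float(num / den)
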