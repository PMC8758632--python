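import numpy as np
import pandas as pd
import pytest

from agrivision import (
    GeneratorConfig,
    VisionBenchmark,
    build_indicator_registry,
    generate_farm_panel,
    generate_landscape_pair,
    load_vision_matrix,
)


@pytest.fixture(scope="session")
def registry():
    return build_indicator_registry()


@pytest.fixture(scope="session")
def visions():
    return load_vision_matrix()


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def default_panel(default_config):
    return generate_farm_panel(default_config)


@pytest.fixture(scope="session")
def default_landscape(default_config):
    return generate_landscape_pair(default_config)


@pytest.fixture(scope="session")
def default_results():
    return VisionBenchmark.from_synthetic(seed=1).fit()


def make_panel(rows):
    """Build a FarmPanel from (farm, indicator, period, value) tuples."""
    from agrivision import FarmPanel

    return FarmPanel(
        pd.DataFrame(rows, columns=["farm_id", "indicator_id", "period", "value"])
    )


@pytest.fixture
def tiny_panel():
    """Three farms with a handful of indicators and one missing pair."""
    rows = [
        ("A", "farm_area", "t0", 20.0), ("A", "farm_area", "t1", 30.0),
        ("B", "farm_area", "t0", 10.0), ("B", "farm_area", "t1", 10.2),
        ("C", "farm_area", "t0", 15.0),  # t1 missing
        ("A", "societal_valuation", "trend", -1),
        ("B", "societal_valuation", "trend", 0),
        ("A", "n_intensity", "t0", 130.0), ("A", "n_intensity", "t1", 131.0),
    ]
    return make_panel(rows)
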