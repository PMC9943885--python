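import numpy as np
import pandas as pd
import pytest

from traitwalls import PipelineConfig, ScenarioConfig


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def small_config():
    """Config whose year range matches the default synthetic scenario."""
    return PipelineConfig(year_start=1, year_end=136)


@pytest.fixture
def records_csv(tmp_path):
    path = tmp_path / "records.csv"
    pd.DataFrame({
        "design_id": ["a", "b", "c"],
        "year": [1830, 1830, 1831],
        "trait_value": [10.0, 12.5, 11.0],
    }).to_csv(path, index=False)
    return path


@pytest.fixture
def events_csv(tmp_path):
    path = tmp_path / "events.csv"
    pd.DataFrame({
        "name": ["electric", "motor_vehicle", "ww1"],
        "year": [1881, 1901, 1914],
        "kind": ["competitor", "competitor", "disturbance"],
    }).to_csv(path, index=False)
    return path


def random_series(rng, n=None, n_min=4):
    """A random but valid sample series for likelihood tests."""
    from traitwalls import SampleSeries
    if n is None:
        n = int(rng.integers(n_min, 11))
    ages = np.cumsum(rng.uniform(0.5, 3.0, size=n))
    return SampleSeries(
        ages=ages - ages[0],
        means=rng.normal(0.0, 5.0, size=n),
        variances=rng.uniform(0.1, 2.0, size=n),
        sizes=rng.integers(2, 30, size=n),
    )
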