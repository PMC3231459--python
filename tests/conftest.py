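import pandas as pd
import pytest

from phenosense import spatial, synth


@pytest.fixture(scope="session")
def site():
    return synth.default_site()


@pytest.fixture(scope="session")
def tower_geom(site):
    """Single phenology tower at the origin."""
    return spatial.layout("transect", site, length=0.0, n=1, sensor_height=5.0)


@pytest.fixture(scope="session")
def small_geom(site):
    """A tower plus two understory nodes."""
    return spatial.layout("transect", site, length=100.0, n=3)


@pytest.fixture(scope="session")
def clean_week(small_geom):
    """Seven defect-free clear-sky days: (table, ground truth)."""
    cfg = synth.SynthConfig(random_seed=11, n_days=7)
    return synth.make_deployment_series(small_geom, cfg)


@pytest.fixture()
def clean_table(clean_week):
    return clean_week[0].copy()


def series_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    cols = ["timestamp", "node_id", "channel", "value"]
    key = ["node_id", "channel", "timestamp"]
    a = a.sort_values(key).reset_index(drop=True)
    b = b.sort_values(key).reset_index(drop=True)
    return a[cols].equals(b[cols])
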