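import numpy as np
import pytest

from capreosex import (
    CandidateDataset,
    SexRatioCount,
    SimulationConfig,
    StudyRecord,
    load_reference_table,
    load_site_table,
    simulate_weather,
)


@pytest.fixture(scope="session")
def site_table():
    """The bundled 15-row secondary-sex-ratio site table."""
    return load_site_table()


@pytest.fixture(scope="session")
def reference_table():
    """The bundled 25-row reference-level table."""
    return load_reference_table()


@pytest.fixture(scope="session")
def small_config():
    """A small, fast simulation: 20 cohorts, 4,000 offspring."""
    return SimulationConfig(seed=11, years=(1995, 2014), n_per_year=200)


@pytest.fixture(scope="session")
def small_weather(small_config):
    return simulate_weather(small_config)


def make_study(n_female, n_male, sid="s", lat=None, lon=None, ratio_type="S"):
    return StudyRecord(
        id=sid,
        reference_id=sid,
        counts=SexRatioCount(n_female=n_female, n_male=n_male),
        latitude=lat,
        longitude=lon,
        ratio_type=ratio_type,
    )


def make_candidate(sid, n_female, n_male, **kwargs):
    return CandidateDataset(
        id=sid, counts=SexRatioCount(n_female=n_female, n_male=n_male), **kwargs
    )
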