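import pytest

import ibdforecast as ib


@pytest.fixture(scope="session")
def asia_table():
    return ib.load_builtin_table()


@pytest.fixture(scope="session")
def iran(asia_table):
    return next(p for p in asia_table if p.region_name == "Iran")


@pytest.fixture(scope="session")
def iran_state(iran):
    return ib.derive_initial_state(iran)


@pytest.fixture(scope="session")
def iran_rates(iran):
    return ib.to_model_rates(iran)


@pytest.fixture
def toy_region():
    """Small synthetic region (1e5 population) for desk-scale checks."""
    return ib.RegionParameters(
        region_name="toy",
        incidence_rate=50.0,
        prevalence_ratio=ib.Uncertain(1000.0, 900.0, 1100.0),
        ibd_death_rate=ib.Uncertain(5.0, 4.0, 6.0),
        background_death_rate=ib.Uncertain(800.0, 700.0, 900.0),
        initial_prevalent_cases=1000.0,
        start_year=2017,
    )
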