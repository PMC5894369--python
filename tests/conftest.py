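import pytest

import tobacco_ecea as te


@pytest.fixture(scope="session")
def profiles():
    return te.load_country_profiles()


@pytest.fixture(scope="session")
def by_name(profiles):
    return {p.name: p for p in profiles}


@pytest.fixture(scope="session")
def schedule():
    return te.fit_life_year_schedule()


@pytest.fixture(scope="session")
def anchored_matrix():
    return te.build_elasticity_matrix()


@pytest.fixture(scope="session")
def replay_table():
    return te.replay_outcomes()


@pytest.fixture(scope="session")
def base_outcomes(profiles):
    """One full default-scenario model run, shared across tests."""
    return te.run_scenario(profiles, te.Scenario(seed=7))
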