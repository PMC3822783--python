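import pytest

from tcellhom import CellState, ModelParams, OntogenyConfig, adult_scenarios, steady_state


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def ontocfg() -> OntogenyConfig:
    return OntogenyConfig()


@pytest.fixture(scope="session")
def equilibrium(params):
    return steady_state(params)


@pytest.fixture(scope="session")
def adult_runs(params):
    """The two published adult scenarios, shared across tests for speed."""
    return adult_scenarios(params, t_end=1000.0)
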