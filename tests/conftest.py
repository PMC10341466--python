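import pytest

from fraudgame.simulate import sample_valid_parameters, scenario_parameters


@pytest.fixture(scope="session")
def scenario1():
    return scenario_parameters(1)


@pytest.fixture(scope="session")
def scenario2():
    return scenario_parameters(2)


@pytest.fixture(scope="session")
def scenario3():
    return scenario_parameters(3)


@pytest.fixture(scope="session")
def random_params_small():
    """50 strictly valid random parameter sets for unit-level properties."""
    return [sample_valid_parameters(seed) for seed in range(50)]


@pytest.fixture(scope="session")
def random_params_large():
    """1000 strictly valid random parameter sets for the property suites."""
    return [sample_valid_parameters(seed) for seed in range(1000)]
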