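import pytest

from guidechart import (
    gestation_risk_automaton,
    gestation_risk_chart,
    ina_statechart,
    refinement_models,
)


@pytest.fixture(scope="session")
def ina():
    return ina_statechart()


@pytest.fixture(scope="session")
def gestation():
    return gestation_risk_chart()


@pytest.fixture(scope="session")
def gestation_auto():
    return gestation_risk_automaton()


@pytest.fixture()
def toys():
    """Refinement family at X initially false."""
    return refinement_models(initial_x=False)


@pytest.fixture()
def toys_x():
    """Refinement family at X initially true (concurrent branch armed)."""
    return refinement_models(initial_x=True)
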