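import numpy as np
import pytest

from gdcea.params import load_default_parameters


@pytest.fixture(scope="session")
def default_params():
    """Packaged parameter fixture: (config, strategies, life table)."""
    return load_default_parameters()


@pytest.fixture(scope="session")
def config(default_params):
    return default_params[0]


@pytest.fixture(scope="session")
def strategies(default_params):
    return default_params[1]


@pytest.fixture(scope="session")
def life_table(default_params):
    return default_params[2]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_strategy(
    label="no_ert",
    transitions=(),
    utility=0.93,
    hospital_cost=0.0,
    ert_cost=0.0,
    production_loss=0.0,
    excess_mortality=0.0,
    start_state=None,
):
    """Minimal fully-populated StrategySpec for engine/economics tests."""
    from gdcea.params import (
        ALIVE_STATES,
        CostSpec,
        DiseaseState,
        StrategySpec,
        TransitionSpec,
        UtilitySpec,
    )

    start_state = start_state or DiseaseState.ASYMPTOMATIC
    utilities = tuple(
        UtilitySpec(s, utility, tariff=t) for s in ALIVE_STATES for t in ("UK", "NL")
    )
    costs = []
    for s in ALIVE_STATES:
        costs.append(CostSpec(s, "hospital", hospital_cost))
        costs.append(CostSpec(s, "out_of_hospital", 0.0))
        costs.append(CostSpec(s, "production_loss", production_loss))
        is_ert_state = label != "no_ert" and s is not DiseaseState.ASYMPTOMATIC
        costs.append(CostSpec(s, "ert", ert_cost if is_ert_state else 0.0))
    return StrategySpec(
        label=label,
        transitions=tuple(
            TransitionSpec(DiseaseState(f), DiseaseState(t), p)
            for f, t, p in transitions
        ),
        utilities=utilities,
        costs=tuple(costs),
        malignancy_excess_mortality=excess_mortality,
        start_distribution={start_state: 1.0},
    )


def flat_life_table(q=0.0, max_age=85):
    from gdcea.params import LifeTable

    return LifeTable(np.full(max_age + 1, q))
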