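import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import swdopt as sw


@pytest.fixture(scope="session")
def alliance_design():
    return sw.make_complete_stepped_wedge(5, [8, 7, 7, 7, 8], 7)


@pytest.fixture(scope="session")
def alliance_costs():
    return sw.CostSpec(
        cost_per_cluster=2500,
        participant_cost_intervention=140,
        participant_cost_control=80,
        restart_cost_intervention=230,
    )


@pytest.fixture(scope="session")
def alliance_corr():
    return sw.CorrelationSpec(icc=0.05, cac=0.95)


@pytest.fixture(scope="session")
def power_spec():
    return sw.PowerSpec(effect_size=0.26, alpha=0.05, min_power=0.80)


@pytest.fixture(scope="session")
def alliance_trace(alliance_design, alliance_corr, alliance_costs, power_spec):
    return sw.greedy_removal_search(
        alliance_design, alliance_corr, alliance_costs, power_spec
    )


@pytest.fixture(scope="session")
def big_design():
    return sw.make_complete_stepped_wedge(14, [1] * 14, 50)


@pytest.fixture(scope="session")
def big_corr():
    return sw.CorrelationSpec(icc=0.15, cac=0.8)


@pytest.fixture(scope="session")
def big_costs_restart():
    return sw.CostSpec(
        cost_per_cluster=2500,
        participant_cost_intervention=80,
        participant_cost_control=80,
        restart_cost_intervention=2500,
    )


@pytest.fixture(scope="session")
def big_costs_norestart():
    return sw.CostSpec(
        cost_per_cluster=2500,
        participant_cost_intervention=140,
        participant_cost_control=80,
    )


@pytest.fixture(scope="session")
def big_trace_restart(big_design, big_corr, big_costs_restart, power_spec):
    return sw.greedy_removal_search(
        big_design, big_corr, big_costs_restart, power_spec
    )


@pytest.fixture(scope="session")
def big_trace_norestart(big_design, big_corr, big_costs_norestart, power_spec):
    return sw.greedy_removal_search(
        big_design, big_corr, big_costs_norestart, power_spec
    )


@pytest.fixture(scope="session")
def alliance_grid():
    return sw.CorrelationGrid((0.01, 0.05, 0.1), (0.8, 0.9, 0.95))


@pytest.fixture(scope="session")
def alliance_superset(alliance_design, alliance_grid, alliance_costs, power_spec):
    return sw.superset_search(
        alliance_design, alliance_grid, alliance_costs, power_spec
    )
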