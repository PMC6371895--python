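import pandas as pd
import pytest
from hypothesis import settings

from streamclass.network import ReachNetwork
from streamclass.synth import (
    GeneratorConfig,
    attach_physical_attributes,
    generate_dendritic_network,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

_REACH_DEFAULTS = {
    "strahler_order": 1,
    "length_km": 1.0,
    "slope": 0.01,
    "mean_annual_q": 1.0,
    "divergence_flag": "none",
    "eco_unit_id": None,
    "inundated_fraction": 0.0,
}


def build_network(reaches, edges=()):
    """Construct a ReachNetwork from minimal per-reach dicts.

    Each dict needs at least ``comid``; all other reach fields default.
    """
    rows = []
    for entry in reaches:
        row = dict(_REACH_DEFAULTS)
        row.update(entry)
        rows.append(row)
    return ReachNetwork(pd.DataFrame(rows), list(edges))


def chain(comids, **common):
    """A linear chain: comids[0] is the headwater, last is the outlet."""
    net = build_network(
        [{"comid": c, **common} for c in comids],
        [(a, b) for a, b in zip(comids, comids[1:])],
    )
    return net


@pytest.fixture
def net_factory():
    return build_network


@pytest.fixture(scope="session")
def generated_network():
    """A 500-reach synthetic network with physical attributes (seed 42)."""
    cfg = GeneratorConfig(seed=42, n_reaches=500)
    return attach_physical_attributes(generate_dendritic_network(cfg), cfg)


@pytest.fixture(scope="session")
def dendritic_network():
    """A strictly dendritic (divergence- and split-free) network."""
    cfg = GeneratorConfig(seed=7, n_reaches=300, divergence_rate=0.0,
                          split_rate=0.0, unflagged_divergence_rate=0.0)
    return attach_physical_attributes(generate_dendritic_network(cfg), cfg)
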