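import numpy as np
import pytest

import planknet as pk
from planknet.balancer import balance_from_rates


@pytest.fixture(scope="session")
def gon_green():
    return pk.gon_model("green")


@pytest.fixture(scope="session")
def gon_blue():
    return pk.gon_model("blue")


@pytest.fixture(scope="session")
def toy_chain3():
    """3-level chain, TE 0.2 per step, basal production 100."""
    return pk.make_toy_chain(3, 0.2, 100.0)


@pytest.fixture(scope="session")
def balanced_chain3(toy_chain3):
    return balance_from_rates(toy_chain3.model, toy_chain3.rates)


@pytest.fixture(scope="session")
def random_web():
    """One representative generated web with planted ground truth."""
    return pk.generate_random_web(pk.WebGeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def balanced_random_web(random_web):
    return balance_from_rates(random_web.model, random_web.rates)


def two_node_nodes():
    """Minimal producer + grazer pair (surface layer)."""
    P = pk.FunctionalNode(
        node_id=1, name="P", trophic_status=pk.TrophicStatus.AUTOTROPH,
        layer=pk.Layer.SURFACE, biomass=100.0, production_rate_range=(0.5, 0.5),
    )
    Z = pk.FunctionalNode(
        node_id=2, name="Z", trophic_status=pk.TrophicStatus.HETEROTROPH,
        layer=pk.Layer.SURFACE, biomass=10.0,
        production_rate_range=(0.03, 0.03), consumption_rate_range=(0.1, 0.1),
        unassimilated_fraction=0.3,
    )
    return P, Z


@pytest.fixture()
def two_node_model():
    P, Z = two_node_nodes()
    diet = pk.DietMatrix([1, 2], {(1, 2): 1.0})
    return pk.build_model([P, Z], diet)
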