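import networkx as nx
import pytest

from fwalign.foodweb import FoodWeb, SpeciesRecord, TrophicLink
from fwalign.synthetic import GeneratorParams, apply_drought, niche_model_web


def make_web(web_id="w", treatment="control", block=1, species=None, links=None):
    """Shorthand web builder: species as (id, role, mass), links as pairs."""
    species = species or [
        ("det1", "detritus", None),
        ("det2", "detritus", None),
        ("alg1", "primary_producer", 0.5),
        ("graz", "herbivore", 2.0),
        ("shred", "detritivore", 3.0),
        ("pred", "predator", 10.0),
    ]
    links = links if links is not None else [
        ("det1", "shred"), ("det2", "shred"), ("alg1", "graz"),
        ("graz", "pred"), ("shred", "pred"),
    ]
    return FoodWeb(
        web_id=web_id,
        treatment=treatment,
        block=block,
        species=[SpeciesRecord(s, name=s, functional_role=r, body_mass=m)
                 for (s, r, m) in species],
        links=[TrophicLink(*l) if not isinstance(l, TrophicLink) else l
               for l in links],
    )


@pytest.fixture
def toy_web():
    return make_web()


@pytest.fixture(scope="session")
def small_control():
    """A compact niche-model web for alignment-heavy tests."""
    return niche_model_web(30, 0.08, seed=21, web_id="C1", block=1)


@pytest.fixture(scope="session")
def small_pair(small_control):
    params = GeneratorParams(
        S=30, C_target=0.08, n_consumer_extinctions_mean=4,
        n_consumer_extinctions_sd=1.0, seed=21,
    )
    return apply_drought(small_control, params, seed=33, web_id="D1")


@pytest.fixture(scope="session")
def default_pair():
    """One pair at the full default generator conditions."""
    control = niche_model_web(74, 98 / 74**2, seed=5, web_id="C1", block=1)
    return apply_drought(control, GeneratorParams(seed=5), seed=6, web_id="D1")


def relabel_disjoint(G: nx.Graph, prefix: str = "b") -> nx.Graph:
    return nx.relabel_nodes(G, {v: f"{prefix}{v}" for v in G.nodes})
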