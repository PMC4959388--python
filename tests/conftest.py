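import pytest

from lbdkit.corpus import Concept, SenseInventory
from lbdkit.synthetic import WorldConfig, build_world, generate_world


@pytest.fixture(scope="session")
def default_world():
    """The shipped default synthetic world (with confounds), seed 1."""
    return build_world(WorldConfig(seed=1))


@pytest.fixture(scope="session")
def small_world():
    """A lighter world for per-test pipelines."""
    config = WorldConfig(
        n_concepts=60,
        n_terms=50,
        n_planted_triples=8,
        n_confounds=2,
        n_docs_pre=200,
        n_docs_post=100,
        seed=7,
    )
    return build_world(config)


@pytest.fixture(scope="session")
def clean_world():
    """Confound-free, distractor-free world: planted structure only."""
    config = WorldConfig(
        n_concepts=60,
        n_terms=60,
        ambiguity_rate=0.0,
        n_planted_triples=10,
        n_confounds=0,
        n_docs_pre=120,
        n_docs_post=60,
        distractor_rate=0.0,
        excluded_type_fraction=0.0,
        seed=3,
    )
    return generate_world(config)


@pytest.fixture()
def cold_inventory():
    """Tiny hand-built inventory with an ambiguous term and a multiword term."""
    common_cold = Concept(cui="C0009443", description="common cold")
    cold_temp = Concept(cui="C0009264", description="cold temperature")
    copd = Concept(cui="C0024117", description="chronic obstructive lung disease")
    fever = Concept(cui="C0015967", description="fever")
    inv = SenseInventory()
    inv.add("cold", common_cold)
    inv.add("cold", cold_temp)
    inv.add("cold", copd)
    inv.add("common cold", common_cold)
    inv.add("fever", fever)
    return inv
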