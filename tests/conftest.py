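import numpy as np
import pytest

from indelrank.rwr import RWRParams
from indelrank.synthetic import (
    SyntheticConfig,
    association_scorers,
    generate_indels,
    generate_world,
    world_networks,
)


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study: 50 diseases, 200 genes, 5 modules,
    20 causal / 200 neutral indels, 3-SD causal effect."""
    cfg = SyntheticConfig(seed=1)
    world = generate_world(cfg)
    indels = generate_indels(cfg, world)
    return cfg, world, indels


@pytest.fixture(scope="session")
def default_scorers(default_fixture):
    _, world, _ = default_fixture
    disease_net, gene_nets = world_networks(world)
    scorers = association_scorers(world, disease_net, gene_nets, seed=1)
    return disease_net, gene_nets, scorers


@pytest.fixture(scope="session")
def small_world():
    """A tiny 12-disease / 30-gene world for exact linear-algebra checks."""
    cfg = SyntheticConfig(
        m_diseases=12, n_genes=30, n_modules=2, n_causal=4, n_neutral=20, seed=3
    )
    world = generate_world(cfg)
    disease_net, gene_nets = world_networks(world, k_disease=5, k_gene=10)
    return cfg, world, disease_net, gene_nets


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tight_params():
    # squared-L2 convergence threshold small enough for 1e-6 agreement
    return RWRParams(eps=1e-16, max_iter=5000)
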