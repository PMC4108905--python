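from __future__ import annotations

import pytest

import phenomatch as pm


@pytest.fixture(scope="session")
def small_world() -> pm.SyntheticWorld:
    """A modest fully-bridged world with the default mixed-fidelity categories."""
    cfg = pm.SyntheticWorldConfig(
        master_seed=11, n_terms=80, n_diseases=30, n_decoy_genes=30
    )
    return pm.generate_world(cfg)


@pytest.fixture(scope="session")
def small_world_scored(small_world):
    ctx, rankings = pm.score_world(small_world)
    return small_world, ctx, rankings


@pytest.fixture()
def chain_ontology():
    """root <- a <- b linear chain."""
    from helpers import make_ontology

    return make_ontology({"root": [], "a": ["root"], "b": ["a"]})
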