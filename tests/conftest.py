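import numpy as np
import pandas as pd
import pytest

import mpdisnet as mp


@pytest.fixture(scope="session")
def two_cliques():
    return mp.load_fixture("two_cliques")


@pytest.fixture(scope="session")
def dense_toy():
    return mp.load_fixture("dense_toy")


@pytest.fixture(scope="session")
def chain_m1_net():
    return mp.load_fixture("chain_m1")


@pytest.fixture(scope="session")
def chain_m3_net():
    return mp.load_fixture("chain_m3")


@pytest.fixture(scope="session")
def mirna_star():
    return mp.load_fixture("mirna_star")


@pytest.fixture(scope="session")
def gene_mediated_dataset():
    """Planted-partition network where clusters share genes but never miRNAs."""
    spec = mp.SyntheticSpec(channel="gene-mediated", seed=1)
    return mp.generate(spec)


@pytest.fixture(scope="session")
def two_cliques_labels():
    """Planted labels for the two_cliques fixture: same-clique positives,
    seeded 1:1 cross-clique negatives."""
    groups = [[f"A{i}" for i in range(1, 6)], [f"B{i}" for i in range(1, 6)]]
    pos = [
        tuple(sorted((g[i], g[j])))
        for g in groups
        for i in range(len(g))
        for j in range(i + 1, len(g))
    ]
    neg = mp.sample_negative_pairs(groups[0] + groups[1], pos, seed=5)
    pos_df = pd.DataFrame(
        [(a, b, 1) for a, b in sorted(pos)],
        columns=["disease_a", "disease_b", "label"],
    )
    return pd.concat([pos_df, neg], ignore_index=True)


@pytest.fixture(scope="session")
def small_corpus(two_cliques):
    """A small deterministic M1 corpus used by several training tests."""
    cfg = mp.WalkConfig(steps_per_walk=4, walks_per_node=30, seed=3)
    return mp.generate_corpus(two_cliques, mp.M1, cfg)
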