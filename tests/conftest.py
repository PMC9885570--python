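import numpy as np
import pytest

from dgnet.network import build_layer, merge_layers


def random_pairs(rng, n_drugs=8, n_genes=15, p=0.25):
    """Random bipartite (drug, gene) pair set with edge probability p."""
    drugs = [f"d{i}" for i in range(n_drugs)]
    genes = [f"g{j}" for j in range(n_genes)]
    mask = rng.uniform(size=(n_drugs, n_genes)) < p
    return {(drugs[i], genes[j]) for i, j in zip(*np.nonzero(mask))}


def random_layered_network(rng, n_drugs=8, n_genes=15, p_target=0.2, p_sensitive=0.3):
    dtn = build_layer(random_pairs(rng, n_drugs, n_genes, p_target), "target")
    dsn = build_layer(random_pairs(rng, n_drugs, n_genes, p_sensitive), "sensitive")
    return merge_layers(dtn, dsn)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
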