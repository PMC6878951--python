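import numpy as np
import pytest

from lucatrace import (
    ScenarioConfig,
    simulate_gene_history,
    simulate_species_tree,
)


@pytest.fixture(scope="session")
def small_species_tree():
    """8+8 taxa, stem 3.0, crown 1.0 — the shape of the study condition."""
    return simulate_species_tree(8, 8, 3.0, 1.0, seed=101)


@pytest.fixture(scope="session")
def vertical_history(small_species_tree):
    return simulate_gene_history(
        small_species_tree, ScenarioConfig(scenario="VERTICAL_LUCA", seed=7)
    )


def patristic_frame(tree):
    """All-pairs tip path lengths as a dict keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            out[(a, b)] = pdm.patristic_distance(taxa[a], taxa[b])
    return out


def assert_same_tree(tree_a, tree_b, tol=1e-9):
    """Unrooted equality of two trees with branch lengths, via the
    patristic distance matrix (positive lengths identify the tree)."""
    da, db = patristic_frame(tree_a), patristic_frame(tree_b)
    assert set(da) == set(db), "tip sets differ"
    for pair in da:
        assert abs(da[pair] - db[pair]) < tol, (pair, da[pair], db[pair])


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
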