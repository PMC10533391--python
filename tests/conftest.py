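import numpy as np
import pandas as pd
import pytest

from invadiv import SyntheticConfig, generate_dataset
from invadiv.trees import TreeIndex

#: ((A:1,B:1):1,C:2); — the standard worked example everywhere
SMALL_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def small_tree() -> TreeIndex:
    return TreeIndex.from_newick(SMALL_NEWICK)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic world shared by read-only tests."""
    cfg = SyntheticConfig(seed=11, n_plots=150, n_species=80)
    return generate_dataset(cfg)


@pytest.fixture
def inventory_frame() -> pd.DataFrame:
    rows = [
        ("t1", "p1", 10.0, 20.0, "Acer_rubrum", 12.0, 9.0, 10.0, 2009),
        ("t2", "p1", 10.0, 20.0, "Pinus_nigra", 30.0, 20.0, 10.0, 2009),
        ("t3", "p1", 10.0, 20.0, "Quercus_alba", 8.0, 6.0, 10.0, 2009),
        ("t4", "p2", 11.0, 21.0, "Acer_rubrum", 15.0, 11.0, 5.0, 2015),
    ]
    return pd.DataFrame(
        rows,
        columns=["tree_id", "plot_id", "lat", "lon", "species",
                 "dbh_cm", "height_m", "tph", "year"],
    )


def brute_force_pd(newick: str, community, include_root=True) -> float:
    """Independent Faith's PD oracle: union of root-to-tip edge sets."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    leaves = {
        leaf.taxon.label.replace(" ", "_"): leaf
        for leaf in tree.leaf_node_iter()
    }
    edge_sets = []
    for name in community:
        edges = set()
        nd = leaves[name]
        while nd.parent_node is not None:
            edges.add(id(nd.edge))
            nd = nd.parent_node
        edge_sets.append(edges)
    union = set().union(*edge_sets)
    if not include_root:
        union -= set.intersection(*edge_sets)
    lengths = {
        id(e): (e.length or 0.0) for e in tree.preorder_edge_iter()
    }
    return sum(lengths[e] for e in union)


def brute_force_mntd(dist: np.ndarray) -> float:
    """Independent MNTD oracle: full pairwise-minimum scan."""
    n = dist.shape[0]
    total = 0.0
    for i in range(n):
        best = np.inf
        for j in range(n):
            if i != j and dist[i, j] < best:
                best = dist[i, j]
        total += best
    return total / n


def brute_force_patristic(newick: str, taxa) -> np.ndarray:
    """Independent patristic oracle via dendropy's distance matrix."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    lookup = {t.label.replace(" ", "_"): t for t in tree.taxon_namespace}
    out = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i != j:
                out[i, j] = pdm.patristic_distance(lookup[a], lookup[b])
    return out
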