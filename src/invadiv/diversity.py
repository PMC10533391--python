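"""Phylogenetic and functional diversity of plot communities.

Two richness/redundancy families are computed in exactly parallel form:

* phylogenetic — Faith's PD (sum of branch lengths spanning the community)
  and MNTD (mean distance to the nearest co-occurring taxon) on a rooted
  reference phylogeny;
* functional — the same two statistics on a dendrogram built by average-
  linkage clustering of Euclidean distances over eight log-transformed,
  standardized traits, so "functional richness" and "functional redundancy"
  are numerically commensurate with their phylogenetic analogues.

Redundancy is reported as (dataset-wide maximum MNTD − community MNTD), so
larger values mean more tightly packed, more redundant communities.  The
invasion-strategy statistic is the relative change in raw MNTD caused by
adding the non-native species:

    strategy = (entire MNTD − native MNTD) / native MNTD

Negative values mean the invaders nest inside the native community
(similarity / environmental filtering); positive values mean they extend it
(dissimilarity / limiting similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .errors import (
    InvalidArgumentError,
    MissingTaxonError,
    UndefinedStatisticError,
)
from .trees import TreeIndex, genus_of

__all__ = [
    "TRAIT_NAMES",
    "transform_traits",
    "patristic_distances",
    "faiths_pd",
    "mntd",
    "redundancy_transform",
    "build_functional_dendrogram",
    "place_genus_level_taxa",
    "PlacementReport",
    "invasion_strategy",
    "CommunityDiversity",
    "community_diversity",
    "diversity_table",
]

#: The eight traits used for the functional axis, chosen to span the major
#: clusters of tree form and function.
TRAIT_NAMES = [
    "wood_density",
    "root_depth",
    "leaf_nitrogen",
    "leaf_phosphorus",
    "leaf_area",
    "tree_height",
    "seed_dry_mass",
    "bark_thickness",
]


def transform_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform then z-score each trait over the species pool.

    Raw trait values must be strictly positive; nonpositive entries are a
    validation error rather than something to offset silently.
    """
    if (traits <= 0).any().any():
        bad = traits.columns[(traits <= 0).any()].tolist()
        raise InvalidArgumentError(
            f"traits must be strictly positive before log transform: {bad}"
        )
    logged = np.log(traits)
    sd = logged.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise InvalidArgumentError("constant trait column cannot be standardized")
    return (logged - logged.mean(axis=0)) / sd


def patristic_distances(tree: TreeIndex, tips: Sequence[str]) -> np.ndarray:
    """Symmetric path-length matrix restricted to ``tips`` (in their order)."""
    idx = tree.indices_of(tips)
    return tree.patristic_matrix()[np.ix_(idx, idx)]


def faiths_pd(tree: TreeIndex, community: Sequence[str], include_root: bool = True) -> float:
    """Faith's phylogenetic diversity of ``community`` on ``tree``."""
    return tree.faiths_pd(community, include_root=include_root)


def mntd(distances: np.ndarray, members: Sequence[int] | None = None) -> float:
    """Mean nearest-taxon distance over a community.

    ``distances`` is a symmetric matrix; ``members`` selects a subset of its
    rows/columns (default: all).  Each member contributes its distance to the
    nearest *other* member.
    """
    d = np.asarray(distances, dtype=float)
    if members is not None:
        idx = np.asarray(members, dtype=int)
        d = d[np.ix_(idx, idx)]
    n = d.shape[0]
    if n < 2:
        raise InvalidArgumentError("MNTD needs at least two community members")
    masked = d + np.diag(np.full(n, np.inf))
    return float(masked.min(axis=1).mean())


def redundancy_transform(mntd_values: np.ndarray | float, reference_max: float):
    """Reflect MNTD into redundancy: reference maximum minus MNTD."""
    out = np.asarray(reference_max, dtype=float) - np.asarray(mntd_values, dtype=float)
    if np.any(out < -1e-12):
        raise InvalidArgumentError(
            "reference_max is smaller than a supplied MNTD value"
        )
    return float(out) if np.isscalar(mntd_values) or np.ndim(mntd_values) == 0 else out


def invasion_strategy(native_mntd_raw: float, entire_mntd_raw: float) -> float:
    """Relative MNTD change caused by the non-native species (see module doc)."""
    if native_mntd_raw <= 0:
        raise UndefinedStatisticError(
            "invasion strategy undefined for native MNTD of zero"
        )
    return (entire_mntd_raw - native_mntd_raw) / native_mntd_raw


# --------------------------------------------------------------------------
# functional dendrogram
# --------------------------------------------------------------------------

def build_functional_dendrogram(
    traits: pd.DataFrame, species: Iterable[str] | None = None
) -> TreeIndex:
    """UPGMA dendrogram over Euclidean distances in transformed trait space.

    ``traits`` must already be log-transformed and standardized (see
    :func:`transform_traits`).  Species with any missing trait are dropped.
    The result is a rooted ultrametric tree reusable by :func:`faiths_pd`
    and :func:`mntd`, whose cophenetic distances realize the UPGMA heights.
    """
    if species is not None:
        species = [s for s in species if s in traits.index]
        traits = traits.loc[species]
    traits = traits.dropna()
    labels = [str(s).replace(" ", "_") for s in traits.index]
    if len(labels) < 2:
        raise InvalidArgumentError("need >=2 species with complete traits")
    z = linkage(pdist(traits.to_numpy(), metric="euclidean"), method="average")
    return _tree_from_linkage(z, labels)


def _tree_from_linkage(z: np.ndarray, labels: list[str]) -> TreeIndex:
    """Turn a scipy linkage matrix into a rooted dendropy tree.

    Node height = merge distance / 2, so cophenetic distance between two
    tips equals the linkage merge distance (tips sit at height 0).
    """
    n = len(labels)
    taxa = dendropy.TaxonNamespace()
    nodes: dict[int, tuple[dendropy.Node, float]] = {}
    for i, lab in enumerate(labels):
        nd = dendropy.Node()
        nd.taxon = taxa.new_taxon(lab)
        nodes[i] = (nd, 0.0)
    for k, (a, b, dist, _) in enumerate(z):
        height = dist / 2.0
        parent = dendropy.Node()
        for child_id in (int(a), int(b)):
            child, child_h = nodes.pop(child_id)
            parent.add_child(child)
            child.edge.length = height - child_h
        nodes[n + k] = (parent, height)
    (root, _), = nodes.values()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return TreeIndex(tree)


# --------------------------------------------------------------------------
# genus-level placement
# --------------------------------------------------------------------------

@dataclass
class PlacementReport:
    species_level: int = 0
    genus_level: int = 0
    unplaced: int = 0
    unplaced_taxa: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": ["species_level", "genus_level", "unplaced"],
                "count": [self.species_level, self.genus_level, self.unplaced],
            }
        )


def place_genus_level_taxa(
    tree: TreeIndex, taxa: Sequence[str]
) -> tuple[TreeIndex, PlacementReport]:
    """Bind taxa to the reference tree, grafting congeners where needed.

    An exact tip match binds at the species level.  A taxon absent from the
    tree but with >=1 congeneric tip is grafted as a new tip at the most
    recent common ancestor of its congeners, with pendant length equal to
    half that node's age (its height above the tips), so the graft stays
    within the tree's depth.  Taxa with no congeners are reported unplaced.
    """
    report = PlacementReport()
    dtree = tree.dendropy_tree.clone(depth=1)
    taxon_ns = dtree.taxon_namespace
    existing = {t.label.replace(" ", "_") for t in taxon_ns}
    grafted = False
    depths = {}  # node -> distance from root

    def node_depth(nd):
        if nd not in depths:
            d, cur = 0.0, nd
            while cur.parent_node is not None:
                d += cur.edge.length or 0.0
                cur = cur.parent_node
            depths[nd] = d
        return depths[nd]

    max_depth = max(node_depth(leaf) for leaf in dtree.leaf_node_iter())

    for raw in taxa:
        name = str(raw).replace(" ", "_")
        if name in existing:
            report.species_level += 1
            continue
        genus = genus_of(name)
        congeners = [
            leaf
            for leaf in dtree.leaf_node_iter()
            if genus_of(leaf.taxon.label) == genus
        ]
        if not congeners:
            report.unplaced += 1
            report.unplaced_taxa.append(name)
            continue
        if len(congeners) == 1:
            attach = congeners[0].parent_node
        else:
            attach = dtree.mrca(taxa=[c.taxon for c in congeners])
        age = max(0.0, max_depth - node_depth(attach))
        new = dendropy.Node()
        new.taxon = taxon_ns.new_taxon(name)
        attach.add_child(new)
        new.edge.length = age / 2.0 if age > 0 else _min_positive_edge(dtree)
        existing.add(name)
        report.genus_level += 1
        grafted = True
        depths.clear()

    return (TreeIndex(dtree) if grafted else tree), report


def _min_positive_edge(dtree) -> float:
    lengths = [e.length for e in dtree.edges() if e.length and e.length > 0]
    return 0.5 * min(lengths) if lengths else 1.0


# --------------------------------------------------------------------------
# per-plot summary
# --------------------------------------------------------------------------

@dataclass
class CommunityDiversity:
    plot_id: str
    native_pd: float
    entire_pd: float
    native_mntd_raw: float
    entire_mntd_raw: float
    func_richness: float
    entire_func_richness: float
    func_mntd_raw: float
    entire_func_mntd_raw: float
    strategy_phylo: float
    strategy_func: float
    native_redundancy: float = np.nan
    func_redundancy: float = np.nan


def community_diversity(
    plot_id: str,
    native_species: Sequence[str],
    entire_species: Sequence[str],
    tree: TreeIndex,
    dendrogram: TreeIndex,
    include_root: bool = True,
) -> CommunityDiversity:
    """All diversity fields for one plot (redundancy filled in later).

    ``native_species`` must be a subset of ``entire_species``; both need at
    least two members placeable on both trees, and at least three members is
    the upstream plot filter.  Raises :class:`MissingTaxonError` when a
    member is absent from either tree, which callers treat as "plot
    excluded", mirroring the removal of incomputable plots.
    """
    native = sorted(set(native_species))
    entire = sorted(set(entire_species))
    if not set(native) <= set(entire):
        raise InvalidArgumentError("native species must be a subset of the community")

    dp = patristic_distances(tree, entire)
    df_ = patristic_distances(dendrogram, entire)
    pos = {s: i for i, s in enumerate(entire)}
    nat_idx = [pos[s] for s in native]

    native_pd = faiths_pd(tree, native, include_root)
    entire_pd = faiths_pd(tree, entire, include_root)
    native_fr = faiths_pd(dendrogram, native, include_root)
    entire_fr = faiths_pd(dendrogram, entire, include_root)
    native_mntd = mntd(dp, nat_idx)
    entire_mntd = mntd(dp)
    native_fm = mntd(df_, nat_idx)
    entire_fm = mntd(df_)

    return CommunityDiversity(
        plot_id=str(plot_id),
        native_pd=native_pd,
        entire_pd=entire_pd,
        native_mntd_raw=native_mntd,
        entire_mntd_raw=entire_mntd,
        func_richness=native_fr,
        entire_func_richness=entire_fr,
        func_mntd_raw=native_fm,
        entire_func_mntd_raw=entire_fm,
        strategy_phylo=invasion_strategy(native_mntd, entire_mntd),
        strategy_func=invasion_strategy(native_fm, entire_fm),
    )


def diversity_table(
    plots: Iterable[tuple[str, Sequence[str], Sequence[str]]],
    tree: TreeIndex,
    dendrogram: TreeIndex,
    include_root: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Two-pass diversity summary over many plots.

    ``plots`` yields ``(plot_id, native_species, entire_species)``.  Pass 1
    computes raw metrics; pass 2 converts native MNTD to redundancy using
    the maximum native MNTD across the analysis set (one reference per
    metric family).  Returns the table and the ids of excluded plots.
    """
    rows, excluded = [], []
    for plot_id, native, entire in plots:
        try:
            cd = community_diversity(
                plot_id, native, entire, tree, dendrogram, include_root
            )
        except (MissingTaxonError, InvalidArgumentError, UndefinedStatisticError):
            excluded.append(str(plot_id))
            continue
        rows.append(cd)
    if not rows:
        return pd.DataFrame(), excluded
    df = pd.DataFrame([r.__dict__ for r in rows])
    max_phylo = df["native_mntd_raw"].max()
    max_func = df["func_mntd_raw"].max()
    df["native_redundancy"] = redundancy_transform(
        df["native_mntd_raw"].to_numpy(), max_phylo
    )
    df["func_redundancy"] = redundancy_transform(
        df["func_mntd_raw"].to_numpy(), max_func
    )
    return df, excluded
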