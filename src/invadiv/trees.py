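"""Rooted branch-length trees and fast edge-based community metrics.

dendropy owns parsing, serialization and tree surgery; this module adds an
edge-incidence index so that Faith's PD and nearest-taxon distances over
thousands of plot communities cost a few vectorized numpy operations each
instead of a tree traversal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import InvalidArgumentError, MissingTaxonError

__all__ = ["TreeIndex", "genus_of"]


def genus_of(label: str) -> str:
    """Genus part of a 'Genus_species' or 'Genus species' label."""
    return label.replace(" ", "_").split("_")[0]


class TreeIndex:
    """A rooted tree flattened into arrays keyed by taxon label.

    Attributes
    ----------
    taxa : list of str
        Tip labels, unique, in a fixed order; row order of all matrices.
    edge_lengths : (n_nodes,) float array
        Length of the edge *above* each node (0 for the root).
    incidence : (n_tips, n_nodes) bool array
        ``incidence[i, v]`` is True when the edge above node ``v`` lies on
        the path from tip ``i`` to the root.
    """

    def __init__(self, dtree: dendropy.Tree):
        dtree = dtree.clone(depth=1)
        dtree.is_rooted = True
        self._dtree = dtree
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): k for k, nd in enumerate(nodes)}
        n_nodes = len(nodes)
        lengths = np.zeros(n_nodes)
        parent = np.full(n_nodes, -1, dtype=int)
        for k, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[k] = index[id(nd.parent_node)]
                lengths[k] = float(nd.edge.length or 0.0)
        tips = [nd for nd in nodes if nd.is_leaf()]
        self.tip_node_indices = np.array([index[id(nd)] for nd in tips], dtype=int)
        labels = [nd.taxon.label.replace(" ", "_") for nd in tips]
        if len(set(labels)) != len(labels):
            raise InvalidArgumentError("tip labels are not unique")
        self.taxa: list[str] = labels
        self._tip_index = {t: i for i, t in enumerate(labels)}
        self.edge_lengths = lengths
        self.parent = parent
        inc = np.zeros((len(tips), n_nodes), dtype=bool)
        for i, nd in enumerate(tips):
            k = index[id(nd)]
            while k != -1:
                inc[i, k] = True
                k = parent[k]
        inc[:, 0] = False  # the root has no edge above it
        self.incidence = inc
        self._dist: np.ndarray | None = None

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_newick(cls, source: str | Path) -> "TreeIndex":
        path = Path(source) if not str(source).lstrip().startswith("(") else None
        if path is not None:
            dtree = dendropy.Tree.get(path=str(path), schema="newick")
        else:
            dtree = dendropy.Tree.get(data=str(source), schema="newick")
        return cls(dtree)

    def to_newick(self) -> str:
        return self._dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    # ------------------------------------------------------------ geometry
    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    @property
    def total_branch_length(self) -> float:
        return float(self.edge_lengths.sum())

    @property
    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, one per taxon."""
        return self.incidence @ self.edge_lengths

    def indices_of(self, taxa: Iterable[str]) -> np.ndarray:
        taxa = [t.replace(" ", "_") for t in taxa]
        missing = [t for t in taxa if t not in self._tip_index]
        if missing:
            raise MissingTaxonError(missing)
        return np.array([self._tip_index[t] for t in taxa], dtype=int)

    def patristic_matrix(self) -> np.ndarray:
        """Full tip-by-tip path-length matrix (cached)."""
        if self._dist is None:
            shared = (self.incidence * self.edge_lengths) @ self.incidence.T
            depth = np.diag(shared)
            d = depth[:, None] + depth[None, :] - 2.0 * shared
            np.fill_diagonal(d, 0.0)
            self._dist = d
        return self._dist

    # -------------------------------------------------------- community ops
    def faiths_pd(self, community: Sequence[str], include_root: bool = True) -> float:
        """Faith's PD: branch length of the subtree spanning ``community``.

        With ``include_root`` (default) the path from the community's MRCA up
        to the tree root is counted, the common convention for rooted PD.
        """
        if len(community) == 0:
            raise InvalidArgumentError("faiths_pd of an empty community")
        idx = self.indices_of(community)
        used = self.incidence[idx]
        any_used = used.any(axis=0)
        pd = float(self.edge_lengths[any_used].sum())
        if not include_root:
            all_used = used.all(axis=0)
            pd -= float(self.edge_lengths[all_used].sum())
        return pd
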