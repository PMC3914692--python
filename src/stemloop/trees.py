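"""Phylogenetic trees: Newick I/O (via dendropy) and the flat postorder
arrays the pruning likelihood consumes.

Branch lengths are in expected substitutions per site.  Because every
model here is reversible, the likelihood does not depend on root
placement; trees may be rooted or unrooted (root of degree 2 or 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["PhyloTree", "TreeArrays"]


@dataclass
class TreeArrays:
    """Postorder traversal of a tree for a fixed taxa ordering.

    Nodes ``0 .. n_taxa-1`` are the leaves in taxa order; internal nodes
    follow in postorder with the root last.  ``children[k]`` lists the
    child node indices of internal node ``k`` (offset by ``n_taxa``), and
    ``lengths[v]`` is the branch above node ``v`` (0 for the root).
    """

    n_taxa: int
    children: list[list[int]]
    lengths: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.n_taxa + len(self.children)


class PhyloTree:
    """Thin wrapper over a dendropy tree."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        t = dendropy.Tree.get(data=text, schema="newick")
        return cls(t)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        t = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(t)

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick", suppress_rooting=True, real_value_format_specifier=".10g"
        )
        return s.strip()

    def write(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- queries -----------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_taxa(self) -> int:
        return len(self._tree.leaf_nodes())

    def branch_lengths(self) -> np.ndarray:
        return np.array(
            [
                e.length if e.length is not None else 0.0
                for e in self._tree.edges()
                if e.head_node is not self._tree.seed_node
            ]
        )

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def scaled(self, factor: float) -> "PhyloTree":
        t = self.clone()
        for e in t._tree.edges():
            if e.length is not None:
                e.length = e.length * factor
        return t

    # -- likelihood support ------------------------------------------------
    def arrays(self, taxa_order: list[str]) -> TreeArrays:
        leaf_index = {name: i for i, name in enumerate(taxa_order)}
        tree_taxa = set(self.taxa)
        if tree_taxa != set(taxa_order):
            missing = tree_taxa ^ set(taxa_order)
            raise ValueError(f"tree/alignment taxa mismatch: {sorted(missing)[:5]}")
        node_id: dict = {}
        children: list[list[int]] = []
        lengths: list[float] = []
        leaf_lengths = np.zeros(len(taxa_order))
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                idx = leaf_index[node.taxon.label]
                node_id[node] = idx
                leaf_lengths[idx] = node.edge.length or 0.0
            else:
                node_id[node] = len(taxa_order) + len(children)
                children.append([node_id[c] for c in node.child_nodes()])
                lengths.append(node.edge.length or 0.0)
        all_lengths = np.concatenate([leaf_lengths, np.array(lengths)])
        arr = TreeArrays(len(taxa_order), children, all_lengths)
        if any(l < 0 for l in all_lengths):
            raise ValueError("negative branch length")
        return arr

    def set_branch_lengths(self, values: np.ndarray, taxa_order: list[str]):
        """Assign branch lengths in the same enumeration order as
        :meth:`arrays` (leaves in taxa order, then internal postorder)."""
        leaf_index = {name: i for i, name in enumerate(taxa_order)}
        n_taxa = len(taxa_order)
        internal = 0
        for node in self._tree.postorder_node_iter():
            if node is self._tree.seed_node:
                continue
            if node.is_leaf():
                node.edge.length = float(values[leaf_index[node.taxon.label]])
            else:
                node.edge.length = float(values[n_taxa + internal])
                internal += 1

    def rerooted_at_edge(self, edge_index: int) -> "PhyloTree":
        t = self.clone()
        edges = [
            e
            for e in t._tree.preorder_edge_iter()
            if e.head_node is not t._tree.seed_node
        ]
        e = edges[edge_index % len(edges)]
        length = e.length or 0.0
        t._tree.reroot_at_edge(e, length1=length / 2, length2=length / 2)
        return t

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree n_taxa={self.n_taxa}>"
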