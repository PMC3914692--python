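"""Comparison of trees and tree sets: normalized Robinson-Foulds distance
and the overlap between two sets of topologies (e.g. posterior samples).

Distances and overlaps are computed on topologies only; branch lengths are
ignored.  A bipartition is represented by the side of the split not
containing a fixed reference taxon, so rooted and unrooted inputs compare
identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .trees import PhyloTree

__all__ = [
    "TreeSet",
    "rf_normalized",
    "set_overlap",
    "mean_pairwise_rf",
    "read_tree_set",
]

#: pairwise products larger than this are subsampled (seeded)
CROSS_PRODUCT_CAP = 10**6


def _splits(tree: PhyloTree) -> frozenset:
    """Non-trivial bipartitions as frozensets of leaf labels (the side not
    containing the lexicographically first taxon)."""
    labels = sorted(tree.taxa)
    ref = labels[0]
    all_taxa = frozenset(labels)
    splits = set()
    for node in tree._tree.preorder_node_iter():
        if node is tree._tree.seed_node or node.is_leaf():
            continue
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        side = all_taxa - clade if ref in clade else clade
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(side)
    return frozenset(splits)


def _check_taxa(a: PhyloTree, b: PhyloTree):
    ta, tb = set(a.taxa), set(b.taxa)
    if ta != tb:
        raise ValueError(f"leaf sets differ: {sorted(ta ^ tb)[:5]}")


def rf_normalized(a: PhyloTree, b: PhyloTree) -> float:
    """Robinson-Foulds bipartition distance scaled to [0, 1]: 0 for
    identical topologies, 1 when no internal branch is shared."""
    _check_taxa(a, b)
    sa, sb = _splits(a), _splits(b)
    denom = len(sa) + len(sb)
    if denom == 0:
        return 0.0
    return len(sa ^ sb) / denom


@dataclass
class TreeSet:
    """A non-empty collection of trees over one shared leaf set."""

    trees: list[PhyloTree]

    def __post_init__(self):
        if not self.trees:
            raise ValueError("tree set is empty")
        first = set(self.trees[0].taxa)
        for t in self.trees[1:]:
            if set(t.taxa) != first:
                raise ValueError("trees in a set must share one leaf set")

    def __len__(self):
        return len(self.trees)

    def topology_keys(self) -> list[frozenset]:
        return [_splits(t) for t in self.trees]


def set_overlap(a: TreeSet, b: TreeSet, dedupe: bool = False) -> float:
    """Proportion of trees whose topology occurs in the other set,
    symmetrized as the mean of the two directed proportions.

    With ``dedupe=True`` the proportions are computed over unique
    topologies instead of tree samples.
    """
    _check_taxa(a.trees[0], b.trees[0])
    ka, kb = a.topology_keys(), b.topology_keys()
    if dedupe:
        ka, kb = list(set(ka)), list(set(kb))
    sa, sb = set(ka), set(kb)
    fwd = sum(k in sb for k in ka) / len(ka)
    rev = sum(k in sa for k in kb) / len(kb)
    return (fwd + rev) / 2.0


def mean_pairwise_rf(a: TreeSet, b: TreeSet, seed: int = 0) -> float:
    """Mean normalized RF distance over the cross-product of the two sets
    (seeded subsample when the product exceeds ``CROSS_PRODUCT_CAP``)."""
    _check_taxa(a.trees[0], b.trees[0])
    ka, kb = a.topology_keys(), b.topology_keys()
    n_pairs = len(ka) * len(kb)
    if n_pairs <= CROSS_PRODUCT_CAP:
        pairs = ((i, j) for i in range(len(ka)) for j in range(len(kb)))
        total = count = 0
        for i, j in pairs:
            denom = len(ka[i]) + len(kb[j])
            total += (len(ka[i] ^ kb[j]) / denom) if denom else 0.0
            count += 1
        return total / count
    rng = np.random.default_rng(seed)
    ii = rng.integers(len(ka), size=CROSS_PRODUCT_CAP)
    jj = rng.integers(len(kb), size=CROSS_PRODUCT_CAP)
    vals = []
    for i, j in zip(ii, jj):
        denom = len(ka[i]) + len(kb[j])
        vals.append((len(ka[i] ^ kb[j]) / denom) if denom else 0.0)
    return float(np.mean(vals))


def read_tree_set(path) -> TreeSet:
    """Read a multi-tree Newick file (one tree per line)."""
    tl = dendropy.TreeList.get(path=str(path), schema="newick")
    return TreeSet([PhyloTree(t) for t in tl])
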