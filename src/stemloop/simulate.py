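"""Synthetic structured RNA alignments evolved under a mixture model.

The simulator draws root states from the stationary frequencies and
propagates them down the tree with exact transition probabilities per
branch (no event-level simulation), exactly matching the process the
likelihood computes.  Loop sites evolve as independent nucleotides; stem
pairs as dinucleotides on branch lengths scaled by ``rho``; Gamma rate
categories are drawn per site or pair.  The stem/loop layout is a single
nested helix flanking the loop block, so every simulated alignment
round-trips through the structure readers.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from ._states import NUC
from .likelihood import MixtureModel
from .structure import PairingMask, StructuredAlignment
from .trees import PhyloTree

__all__ = ["SimulationSpec", "simulate_alignment", "random_tree"]


@dataclass
class SimulationSpec:
    """Everything that determines one simulated alignment; the seed fully
    determines the output."""

    mix: MixtureModel
    n_loop_sites: int
    n_pairs: int
    seed: int = 0
    tree: PhyloTree | None = None
    n_taxa: int | None = None
    branch_length_mean: float = 0.1


def random_tree(
    n_taxa: int,
    branch_length_distribution="exponential",
    seed: int = 0,
    mean: float = 0.1,
) -> PhyloTree:
    """Uniform random unrooted binary topology (random sequential addition)
    with i.i.d. branch lengths.

    ``branch_length_distribution`` is ``"exponential"``, ``"uniform"`` or a
    callable ``f(rng) -> float``.
    """
    if n_taxa < 3:
        raise ValueError(f"need at least 3 taxa, got {n_taxa}")
    rng = np.random.default_rng(seed)
    if callable(branch_length_distribution):
        draw = branch_length_distribution
    elif branch_length_distribution == "exponential":
        draw = lambda r: float(r.exponential(mean))  # noqa: E731
    elif branch_length_distribution == "uniform":
        draw = lambda r: float(r.uniform(0.0, 2.0 * mean))  # noqa: E731
    else:
        raise ValueError(f"unknown distribution {branch_length_distribution!r}")
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    for name in taxa[:3]:
        child = tree.seed_node.new_child()
        child.taxon = tns.get_taxon(name)
    for name in taxa[3:]:
        edges = [
            e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node
        ]
        target = edges[rng.integers(len(edges))]
        head = target.head_node
        parent = head.parent_node
        parent.remove_child(head)
        mid = parent.new_child()
        mid.add_child(head)
        leaf = mid.new_child()
        leaf.taxon = tns.get_taxon(name)
    for e in tree.preorder_edge_iter():
        if e.head_node is not tree.seed_node:
            e.length = draw(rng)
    return PhyloTree(tree)


def _evolve(model, tree: PhyloTree, n_sites: int, branch_scale: float, rng):
    """Site-wise states at every leaf; returns (n_taxa, n_sites) ints in the
    model's state space, with taxa in ``tree.taxa`` order."""
    gr = model.gamma_rates()
    cats = rng.integers(len(gr.rates), size=n_sites)
    dtree = tree._tree
    states: dict = {}
    root = dtree.seed_node
    states[root] = rng.choice(model.n_states, size=n_sites, p=model.pi / model.pi.sum())
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        t = (node.edge.length or 0.0) * branch_scale
        parent_states = states[node.parent_node]
        child = np.empty(n_sites, dtype=np.int64)
        for c, rate in enumerate(gr.rates):
            P = model.transition(t, rate)
            cum = np.cumsum(P, axis=1)
            sel = cats == c
            if not sel.any():
                continue
            u = rng.random(sel.sum())
            child[sel] = np.minimum(
                (u[:, None] > cum[parent_states[sel]]).sum(axis=1),
                model.n_states - 1,
            )
        states[node] = child
    leaf_order = tree.taxa
    out = np.empty((len(leaf_order), n_sites), dtype=np.int64)
    for leaf in dtree.leaf_node_iter():
        out[leaf_order.index(leaf.taxon.label)] = states[leaf]
    return out


def simulate_alignment(spec: SimulationSpec):
    """Evolve an alignment; returns (StructuredAlignment, truth record).

    The truth record stores every generating choice: the tree (newick),
    the mixture, and the seed.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    if tree is None:
        if spec.n_taxa is None:
            raise ValueError("either a tree or n_taxa must be given")
        tree = random_tree(
            spec.n_taxa, seed=int(rng.integers(2**31 - 1)), mean=spec.branch_length_mean
        )
    mix = spec.mix
    n_loop, n_pairs = spec.n_loop_sites, spec.n_pairs
    n_cols = n_loop + 2 * n_pairs
    taxa = tree.taxa
    grid = np.empty((len(taxa), n_cols), dtype="<U1")

    pair_cols = [(k, n_cols - 1 - k) for k in range(n_pairs)]
    loop_cols = list(range(n_pairs, n_pairs + n_loop))

    if not mix.partitioned:
        sites = _evolve(mix.loop_model, tree, n_cols, 1.0, rng)
        for col in range(n_cols):
            grid[:, col] = [NUC[s] for s in sites[:, col]]
    else:
        if n_loop:
            loop_states = _evolve(mix.loop_model, tree, n_loop, 1.0, rng)
            for idx, col in enumerate(loop_cols):
                grid[:, col] = [NUC[s] for s in loop_states[:, idx]]
        if n_pairs:
            stem = mix.stem_model
            if stem.n_states == 4:
                nuc_states = _evolve(stem, tree, 2 * n_pairs, mix.rho, rng)
                for k, (i, j) in enumerate(pair_cols):
                    grid[:, i] = [NUC[s] for s in nuc_states[:, 2 * k]]
                    grid[:, j] = [NUC[s] for s in nuc_states[:, 2 * k + 1]]
            else:
                if stem.n_states == 7:
                    # the MM state has no unique letters; emit from the
                    # equivalent 16-state projection with equal mismatch
                    # shares and instantaneous mismatch exchange
                    from ._states import MM7
                    from .projection import project_7_to_16

                    stem = project_7_to_16(
                        stem, np.full(10, stem.pi[MM7] / 10.0)
                    )
                pair_states = _evolve(stem, tree, n_pairs, mix.rho, rng)
                for k, (i, j) in enumerate(pair_cols):
                    grid[:, i] = [NUC[s // 4] for s in pair_states[:, k]]
                    grid[:, j] = [NUC[s % 4] for s in pair_states[:, k]]

    mask = PairingMask(tuple(pair_cols), tuple(loop_cols))
    aln = StructuredAlignment(
        taxa=list(taxa), rows=["".join(row) for row in grid], mask=mask
    )
    truth = {
        "seed": spec.seed,
        "tree": tree.to_newick(),
        "partitioned": mix.partitioned,
        "rho": mix.rho,
        "loop_model": mix.loop_model.name,
        "loop_gamma_shape": mix.loop_model.gamma_shape,
        "stem_model": None if mix.stem_model is None else mix.stem_model.name,
        "stem_gamma_shape": None if mix.stem_model is None else mix.stem_model.gamma_shape,
        "n_loop_sites": n_loop,
        "n_pairs": n_pairs,
        "mixture": mix,
        "phylo_tree": tree,
    }
    return aln, truth
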