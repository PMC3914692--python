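"""Shared test utilities: independent oracles and random-input builders.

The brute-force likelihood here enumerates all internal-node state
assignments explicitly; it shares no code path with the pruning recursion
it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

import stemloop as sl
from stemloop._states import NUC, STRAND_SWAP7
from stemloop.models import SubstitutionModel


def brute_force_loglik(tree, model, patterns, weights, taxa, branch_scale=1.0):
    """lnL by explicit summation over all internal-node state assignments."""
    arr = tree.arrays(taxa)
    gr = model.gamma_rates()
    n = model.n_states
    internal = list(range(arr.n_taxa, arr.n_nodes))
    root = arr.n_nodes - 1
    total = 0.0
    for p in range(patterns.shape[1]):
        site = 0.0
        for rate, wcat in zip(gr.rates, gr.weights):
            P = [
                model.transition(arr.lengths[v], rate * branch_scale)
                for v in range(arr.n_nodes)
            ]
            cat_sum = 0.0
            for assign in itertools.product(range(n), repeat=len(internal)):
                amap = dict(zip(internal, assign))
                prob = model.pi[amap[root]]
                for k, kids in enumerate(arr.children):
                    node = arr.n_taxa + k
                    for child in kids:
                        if child < arr.n_taxa:
                            obs = patterns[child, p]
                            prob *= 1.0 if obs < 0 else P[child][amap[node], obs]
                        else:
                            prob *= P[child][amap[node], amap[child]]
                cat_sum += prob
            site += wcat * cat_sum
        total += weights[p] * np.log(site)
    return total


def random_frequencies(rng, structure: str, n_states: int):
    """Random valid frequency parameters for one frequency structure."""
    if structure == "stable_sets":
        nuc_pi = rng.dirichlet(np.full(4, 5.0))
        return {
            "nuc_pi": nuc_pi,
            "alpha": float(rng.uniform(0.5, 8.0)),
            "beta": float(rng.uniform(0.5, 4.0)),
        }
    if structure == "strand_symmetric":
        masses = rng.dirichlet(np.full(4, 5.0))  # AU/UA, GU/UG, GC/CG, MM
        pi = np.empty(7)
        pi[6] = masses[3]
        for idx, m in zip((0, 1, 2), masses[:3]):
            pi[idx] = pi[STRAND_SWAP7[idx]] = m / 2.0
        return {"pi": pi}
    if structure == "pooled_mismatch":
        masses = rng.dirichlet(np.full(7, 5.0))
        pi = np.empty(16)
        from stemloop._states import CANONICAL16_INDICES, MISMATCH16_INDICES

        pi[CANONICAL16_INDICES] = masses[:6]
        pi[MISMATCH16_INDICES] = masses[6] / 10.0
        return {"pi": pi}
    return {"pi": rng.dirichlet(np.full(n_states, 5.0))}


def random_model(name: str, rng, gamma: bool = False) -> SubstitutionModel:
    """A registered model with random valid parameters."""
    desc = sl.descriptor(name)
    params = random_frequencies(rng, desc.frequency_structure, desc.n_states)
    params["rates"] = {
        c: float(rng.uniform(0.2, 4.0)) for c in desc.rate_class_names
    }
    if gamma:
        params["gamma_shape"] = float(rng.uniform(0.3, 3.0))
    return sl.build_model(name, params)


def random_structured_alignment(
    rng, n_taxa=6, n_pairs=10, n_loop=8, gap_prob=0.05
) -> sl.StructuredAlignment:
    """Random (not tree-generated) letters on a nested-helix layout; valid
    input for any likelihood, suited to algebraic-identity checks."""
    n_cols = 2 * n_pairs + n_loop
    alphabet = list(NUC) + ["-"]
    probs = [(1 - gap_prob) / 4] * 4 + [gap_prob]
    grid = rng.choice(alphabet, size=(n_taxa, n_cols), p=probs)
    pairs = tuple((k, n_cols - 1 - k) for k in range(n_pairs))
    loops = tuple(range(n_pairs, n_pairs + n_loop))
    rows = ["".join(r) for r in grid]
    taxa = [f"t{i + 1}" for i in range(n_taxa)]
    return sl.StructuredAlignment(taxa, rows, sl.PairingMask(pairs, loops))


def alignment_with_mismatches(n_mismatch: int) -> sl.StructuredAlignment:
    """Alignment whose stem contains exactly ``n_mismatch`` unambiguous
    mismatch observations (3 taxa x 7 pairs = 21 slots)."""
    n_taxa, n_pairs = 3, 7
    slots = [(t, k) for t in range(n_taxa) for k in range(n_pairs)]
    assert n_mismatch <= len(slots)
    n_cols = 2 * n_pairs + 4
    grid = [["A"] * n_cols for _ in range(n_taxa)]
    for t in range(n_taxa):
        for k in range(n_pairs):
            grid[t][k] = "G"
            grid[t][n_cols - 1 - k] = "C"
    for t, k in slots[:n_mismatch]:
        grid[t][k] = "A"
        grid[t][n_cols - 1 - k] = "A"  # AA is a mismatch
    pairs = tuple((k, n_cols - 1 - k) for k in range(n_pairs))
    loops = tuple(range(n_pairs, n_pairs + 4))
    return sl.StructuredAlignment(
        [f"t{i + 1}" for i in range(n_taxa)],
        ["".join(r) for r in grid],
        sl.PairingMask(pairs, loops),
    )
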