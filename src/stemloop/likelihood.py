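"""Partitioned mixture log-likelihoods on a fixed tree, and their
maximization.

The likelihood is the standard pruning recursion over a fixed topology.
Loop columns are scored under a 4-state nucleotide model; stem column
pairs under a 4-, 7- or 16-state model with branch lengths multiplied by
the relative stem rate ``rho``.  Discrete-Gamma rate heterogeneity mixes
equal-weight rate categories at the site (or pair) level.  Ambiguous leaf
observations carry a partial-likelihood vector of ones.

ML fitting holds frequencies at their empirical counts (never optimized)
and maximizes exchangeabilities, Gamma shapes, ``rho``, Stable Sets
``alpha``/``beta`` and optionally branch lengths by bounded quasi-Newton
with multiple restarts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from . import models as _models
from .models import SubstitutionModel, build_model, empirical_params
from .structure import EncodedPartition
from .trees import PhyloTree, TreeArrays

__all__ = [
    "MixtureModel",
    "MixtureSpec",
    "FitResult",
    "transition_matrix",
    "prune_loglik",
    "partition_loglik",
    "fit_ml",
    "gene_rate",
]


@dataclass
class MixtureModel:
    """Loop foundation model + stem foundation model + relative stem rate.

    ``partitioned=False`` means a single 4-state model (held in
    ``loop_model``) covers every column and ``rho`` is meaningless.
    """

    loop_model: SubstitutionModel
    stem_model: SubstitutionModel | None = None
    rho: float = 1.0
    partitioned: bool = True

    def __post_init__(self):
        if self.partitioned:
            if self.stem_model is None:
                raise ValueError("partitioned mixture requires a stem model")
            if self.rho <= 0:
                raise ValueError(f"rho must be > 0, got {self.rho}")


def transition_matrix(model: SubstitutionModel, t: float, rate: float = 1.0) -> np.ndarray:
    """P = exp(Q t rate); rows sum to one, P(0) is the identity."""
    return model.transition(t, rate)


# ---------------------------------------------------------------------------
# pruning


def prune_loglik(
    arr: TreeArrays,
    model: SubstitutionModel,
    patterns: np.ndarray,
    weights: np.ndarray,
    branch_scale: float = 1.0,
) -> float:
    """Felsenstein pruning over compressed site patterns.

    ``patterns`` has shape (n_taxa, n_patterns) with state codes or -1 for
    fully ambiguous; ``weights`` are pattern multiplicities.
    """
    n_pat = patterns.shape[1]
    if n_pat == 0:
        return 0.0
    n = model.n_states
    gr = model.gamma_rates()
    n_internal = len(arr.children)
    cat_loglik = np.empty((len(gr.rates), n_pat))
    for c, rate in enumerate(gr.rates):
        P = [
            model.transition(arr.lengths[v], rate * branch_scale)
            for v in range(arr.n_nodes)
        ]
        partial = [None] * arr.n_nodes
        scale = [None] * arr.n_nodes
        for k in range(n_internal):
            node = arr.n_taxa + k
            part = np.ones((n_pat, n))
            logs = np.zeros(n_pat)
            for child in arr.children[k]:
                if child < arr.n_taxa:
                    obs = patterns[child]
                    contrib = np.ones((n_pat, n))
                    seen = obs >= 0
                    contrib[seen] = P[child][:, obs[seen]].T
                else:
                    contrib = partial[child] @ P[child].T
                    logs += scale[child]
                part *= contrib
            m = part.max(axis=1)
            m[m <= 0.0] = 1.0
            part /= m[:, None]
            partial[node] = part
            scale[node] = logs + np.log(m)
        root = arr.n_nodes - 1
        lik = partial[root] @ model.pi
        with np.errstate(divide="ignore"):
            cat_loglik[c] = np.log(lik) + scale[root]
    site_loglik = logsumexp(cat_loglik, axis=0, b=gr.weights[:, None])
    return float(site_loglik @ weights)


def partition_loglik(tree: PhyloTree, mix: MixtureModel, enc: EncodedPartition) -> float:
    """Total log-likelihood of the stem/loop mixture on a fixed tree."""
    arr = tree.arrays(enc.taxa)
    if not mix.partitioned:
        if mix.loop_model.n_states != 4:
            raise ValueError("unpartitioned scoring requires a 4-state model")
        patterns, weights = enc.compressed("all_nuc")
        return prune_loglik(arr, mix.loop_model, patterns, weights)
    if enc.n_loop == 0 or enc.n_pairs == 0:
        raise ValueError(
            f"partitioned mixture needs both partitions: "
            f"{enc.n_loop} loop columns, {enc.n_pairs} pairs"
        )
    lp, lw = enc.compressed("loop")
    total = prune_loglik(arr, mix.loop_model, lp, lw)
    stem = mix.stem_model
    which = {4: "stem_nuc", 7: "stem7", 16: "stem16"}[stem.n_states]
    sp, sw = enc.compressed(which)
    total += prune_loglik(arr, stem, sp, sw, branch_scale=mix.rho)
    return total


# ---------------------------------------------------------------------------
# model specification and fitting


def _split_gamma(name: str) -> tuple[str, bool]:
    if name.endswith("+G"):
        return name[:-2], True
    return name, False


@dataclass(frozen=True)
class MixtureSpec:
    """Names-only description of one candidate mixture.

    Model names may carry a ``+G`` suffix for discrete-Gamma rates.  For an
    unpartitioned candidate the single nucleotide model sits in
    ``loop_name`` and ``stem_name`` is None.
    """

    loop_name: str = "HKY+G"
    stem_name: str | None = None
    partitioned: bool = True
    n_gamma_cats: int = 4

    @property
    def stem_gamma(self) -> bool:
        return self.stem_name is not None and _split_gamma(self.stem_name)[1]

    @property
    def stem_base(self) -> str | None:
        return None if self.stem_name is None else _split_gamma(self.stem_name)[0]

    @property
    def stem_states(self) -> int | None:
        if self.stem_name is None:
            return None
        return _models.descriptor(self.stem_base).n_states

    @property
    def name(self) -> str:
        if not self.partitioned:
            return f"{self.loop_name} (single)"
        return f"{self.loop_name}|{self.stem_name}"


@dataclass
class FitResult:
    """Outcome of one maximum-likelihood fit."""

    lnL: float
    params: dict
    k: int
    n: int
    correction: str = "none"
    aicc: float = float("nan")
    converged: bool = True
    spec: MixtureSpec | None = None
    mixture: MixtureModel | None = None


@dataclass
class _Free:
    key: str
    init: float
    lo: float
    hi: float


def _rate_free_params(desc, prefix: str) -> list[_Free]:
    names = desc.rate_class_names
    # the first class is the reference rate, fixed at 1 by the overall
    # scaling of Q; the rest are free
    return [_Free(f"{prefix}:{c}", 1.0, 1e-4, 1e4) for c in names[1:]]


def _build_component(
    base: str, freq_params: Mapping, values: Mapping[str, float], prefix: str,
    gamma: bool, n_gamma_cats: int,
) -> SubstitutionModel:
    desc = _models.descriptor(base)
    rates = {
        c: values.get(f"{prefix}:{c}", 1.0) for c in desc.rate_class_names
    }
    params = dict(freq_params)
    if desc.frequency_structure == "stable_sets":
        params["alpha"] = values.get(f"{prefix}:alpha", params.get("alpha", 1.0))
        params["beta"] = values.get(f"{prefix}:beta", params.get("beta", 1.0))
    params["rates"] = rates
    if gamma:
        params["gamma_shape"] = values.get(f"{prefix}:shape", 1.0)
        params["n_gamma_cats"] = n_gamma_cats
    return build_model(base, params)


def fit_ml(
    tree: PhyloTree,
    spec: MixtureSpec,
    enc: EncodedPartition,
    optimize_branch_lengths: bool = False,
    n_starts: int = 3,
    seed: int = 0,
    pseudocount: float = 0.5,
    include_branch_lengths_in_k: bool = True,
) -> FitResult:
    """Maximize the mixture log-likelihood over free parameters.

    Frequencies are fixed at empirical counts.  Free parameters (all
    positive) are optimized on the log scale with L-BFGS-B from
    ``n_starts`` starting points (defaults, then seeded perturbations).
    Non-convergence of every start flags the result rather than raising.
    """
    from .selection import aicc as _aicc  # local import; selection builds on us

    loop_base, loop_gamma = _split_gamma(spec.loop_name)
    region = "loop" if spec.partitioned else "all"
    loop_freqs = empirical_params(loop_base, enc, region=region, pseudocount=pseudocount)

    free: list[_Free] = [
        *_rate_free_params(_models.descriptor(loop_base), "loop"),
    ]
    if loop_gamma:
        free.append(_Free("loop:shape", 1.0, 0.02, 100.0))

    stem_freqs: Mapping | None = None
    if spec.partitioned:
        if enc.n_loop == 0 or enc.n_pairs == 0:
            raise ValueError("partitioned fit needs non-empty loop and stem partitions")
        stem_base = spec.stem_base
        stem_desc = _models.descriptor(stem_base)
        stem_freqs = empirical_params(stem_base, enc, region="stem", pseudocount=pseudocount)
        free.extend(_rate_free_params(stem_desc, "stem"))
        if stem_desc.frequency_structure == "stable_sets":
            free.append(_Free("stem:alpha", stem_freqs["alpha"], 1e-3, 1e3))
            free.append(_Free("stem:beta", stem_freqs["beta"], 1e-3, 1e3))
        if spec.stem_gamma:
            free.append(_Free("stem:shape", 1.0, 0.02, 100.0))
        free.append(_Free("rho", 1.0, 1e-3, 1e3))

    arr = tree.arrays(enc.taxa)
    n_branch_free = 0
    branch_init = None
    if optimize_branch_lengths:
        branch_init = np.maximum(arr.lengths[:-1], 1e-6)  # root slot excluded
        n_branch_free = branch_init.size
        for b, t0 in enumerate(branch_init):
            free.append(_Free(f"branch:{b}", float(t0), 1e-7, 20.0))

    work_tree = tree

    def unpack(x: np.ndarray) -> dict[str, float]:
        return {f.key: float(np.exp(v)) for f, v in zip(free, x)}

    def mixture_for(values: Mapping[str, float]) -> MixtureModel:
        loop_model = _build_component(
            loop_base, loop_freqs, values, "loop", loop_gamma, spec.n_gamma_cats
        )
        if not spec.partitioned:
            return MixtureModel(loop_model, None, 1.0, partitioned=False)
        stem_model = _build_component(
            spec.stem_base, stem_freqs, values, "stem", spec.stem_gamma,
            spec.n_gamma_cats,
        )
        return MixtureModel(loop_model, stem_model, values.get("rho", 1.0), True)

    def objective(x: np.ndarray) -> float:
        values = unpack(x)
        if optimize_branch_lengths:
            bl = np.array([values[f"branch:{b}"] for b in range(n_branch_free)])
            full = np.concatenate([bl, [0.0]])
            t = work_tree.clone()
            t.set_branch_lengths(full, enc.taxa)
            target_tree = t
        else:
            target_tree = work_tree
        try:
            mix = mixture_for(values)
            lnL = partition_loglik(target_tree, mix, enc)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        if not np.isfinite(lnL):
            return 1e12
        return -lnL

    rng = np.random.default_rng(seed)
    x0 = np.log([f.init for f in free])
    bounds = [(np.log(f.lo), np.log(f.hi)) for f in free]
    best = None
    converged = False
    for s in range(max(1, n_starts)):
        start = x0 if s == 0 else np.clip(
            x0 + rng.normal(0.0, 0.5, size=x0.shape),
            [b[0] for b in bounds],
            [b[1] for b in bounds],
        )
        if free:
            res = minimize(
                objective,
                start,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-6},
            )
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)
        else:
            val = objective(start)
            best = dataclasses.make_dataclass("R", ["x", "fun"])(start, val)
            converged = True

    values = unpack(best.x)
    mix = mixture_for(values)
    final_tree = work_tree
    if optimize_branch_lengths:
        bl = np.array([values[f"branch:{b}"] for b in range(n_branch_free)])
        final_tree = work_tree.clone()
        final_tree.set_branch_lengths(np.concatenate([bl, [0.0]]), enc.taxa)
    lnL = partition_loglik(final_tree, mix, enc)

    k = _models.descriptor(loop_base).free_param_count + int(loop_gamma)
    if spec.partitioned:
        k += _models.descriptor(spec.stem_base).free_param_count
        k += int(spec.stem_gamma) + 1  # stem shape and rho
    if optimize_branch_lengths and include_branch_lengths_in_k:
        k += n_branch_free

    n = enc.n_loop + enc.n_pairs
    params = dict(values)
    params["loop_pi"] = mix.loop_model.pi.copy()
    if spec.partitioned:
        if _models.descriptor(spec.stem_base).frequency_structure == "stable_sets":
            params["stem_nuc_pi"] = np.asarray(stem_freqs["nuc_pi"]).copy()
        params["stem_pi"] = mix.stem_model.pi.copy()
    result = FitResult(
        lnL=lnL,
        params=params,
        k=k,
        n=n,
        correction="none",
        aicc=_aicc(lnL, k, n),
        converged=converged,
        spec=spec,
        mixture=mix,
    )
    if optimize_branch_lengths:
        result.params["tree"] = final_tree
    return result


def gene_rate(mix: MixtureModel, p_stem: float) -> float:
    """Per-nucleotide substitution rate of the whole gene, in units of the
    loop rate.

    Dinucleotide stem models are scaled to one substitution per
    dinucleotide, i.e. one half per nucleotide, hence the factor 2 in the
    conversion; nucleotide stem models are already per site.
    """
    if not (0.0 <= p_stem <= 1.0):
        raise ValueError(f"p_stem must be in [0, 1], got {p_stem}")
    if not mix.partitioned or p_stem == 0.0:
        return 1.0
    per_nuc = mix.rho / 2.0 if mix.stem_model.n_states > 4 else mix.rho
    return (1.0 - p_stem) * 1.0 + p_stem * per_nuc
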