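"""Foundation substitution models on 4-, 7- and 16-state spaces.

Every model is a time-reversible Markov process with rate matrix
``Q = S diag(pi)`` (off-diagonal), where ``S`` is a symmetric matrix of
exchangeabilities and ``pi`` the equilibrium frequencies, so that detailed
balance ``pi_i q_ij = pi_j q_ji`` holds by construction.  Matrices are
scaled to one expected substitution per unit time per character in their
own space: per site for 4-state models, per dinucleotide for 7- and
16-state models.

The registry of 18 foundation models (HKY, GTR, 7A-7G, 16A-16F, 16I-16K)
is declarative: see :mod:`stemloop._registry_defs`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._registry_defs import NESTINGS, ModelDescriptor, builtin_descriptors
from ._states import (
    DINUC16,
    MISMATCH16_INDICES,
    STRAND_SWAP7,
    WATSON_CRICK,
    WOBBLE,
)

__all__ = [
    "GammaRates",
    "StableSetsParams",
    "SubstitutionModel",
    "registry",
    "descriptor",
    "build_rate_matrix",
    "discretize_gamma",
    "stable_sets_frequencies",
    "build_model",
    "empirical_frequencies",
    "empirical_params",
    "export_descriptors",
    "NESTINGS",
]

_REGISTRY: dict[str, ModelDescriptor] = builtin_descriptors()


def registry() -> dict[str, ModelDescriptor]:
    """Name -> descriptor mapping for all registered foundation models."""
    return dict(_REGISTRY)


def descriptor(name: str) -> ModelDescriptor:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def export_descriptors(directory) -> list[str]:
    """Write one human-readable YAML descriptor file per model."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, desc in sorted(_REGISTRY.items()):
        path = directory / f"{name}.yaml"
        path.write_text(desc.to_yaml())
        written.append(str(path))
    return written


def packaged_descriptor(name: str) -> ModelDescriptor:
    """Load a descriptor from the YAML files shipped with the package."""
    text = (
        importlib.resources.files("stemloop")
        .joinpath("descriptors", f"{name}.yaml")
        .read_text()
    )
    return ModelDescriptor.from_yaml(text)


# ---------------------------------------------------------------------------
# gamma rate heterogeneity


@dataclass(frozen=True)
class GammaRates:
    """Discrete approximation of Gamma(shape, shape) rates-across-sites:
    equal-probability categories, each category carrying the mean of the
    density over its quantile bin (so the overall mean rate is one)."""

    shape: float
    rates: np.ndarray
    weights: np.ndarray


def discretize_gamma(shape: float, n_cats: int = 4) -> GammaRates:
    if shape <= 0:
        raise ValueError(f"gamma shape must be > 0, got {shape}")
    if n_cats < 1:
        raise ValueError(f"n_cats must be >= 1, got {n_cats}")
    if n_cats == 1:
        return GammaRates(shape, np.array([1.0]), np.array([1.0]))
    probs = np.arange(1, n_cats) / n_cats
    edges = gamma_dist.ppf(probs, a=shape, scale=1.0 / shape)
    # E[X; X in bin] for X ~ Gamma(a, 1/a) is the regularized incomplete
    # gamma of shape a+1 evaluated at the bin edges (mean of X is 1)
    upper = np.concatenate([gammainc(shape + 1.0, shape * edges), [1.0]])
    lower = np.concatenate([[0.0], gammainc(shape + 1.0, shape * edges)])
    rates = n_cats * (upper - lower)
    weights = np.full(n_cats, 1.0 / n_cats)
    return GammaRates(shape, rates, weights)


# ---------------------------------------------------------------------------
# stable-sets frequencies


@dataclass(frozen=True)
class StableSetsParams:
    """Stable Sets frequency parameterization: the frequency of dinucleotide
    XY is ``alpha pi_X pi_Y / lam`` for Watson-Crick pairs, ``beta pi_X pi_Y
    / lam`` for wobble pairs and ``pi_X pi_Y / lam`` for mismatches, with
    ``lam`` normalizing the sum to one."""

    nuc_pi: np.ndarray
    alpha: float
    beta: float
    lam: float = field(default=float("nan"))


def stable_sets_frequencies(p: StableSetsParams) -> tuple[np.ndarray, float]:
    nuc_pi = np.asarray(p.nuc_pi, dtype=float)
    if nuc_pi.shape != (4,) or abs(nuc_pi.sum() - 1.0) > 1e-8 or (nuc_pi <= 0).any():
        raise ValueError("nuc_pi must be 4 positive frequencies summing to 1")
    if p.alpha <= 0 or p.beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    boost = np.ones(16)
    for d in WATSON_CRICK:
        boost[DINUC16.index(d)] = p.alpha
    for d in WOBBLE:
        boost[DINUC16.index(d)] = p.beta
    raw = boost * np.outer(nuc_pi, nuc_pi).ravel()
    lam = raw.sum()
    return raw / lam, float(lam)


# ---------------------------------------------------------------------------
# rate matrices


def build_rate_matrix(
    pi: np.ndarray, S: np.ndarray, scale_unit: str = "per-site"
) -> np.ndarray:
    """Reversible rate matrix ``Q = S diag(pi)``, scaled to one expected
    substitution per character (site or dinucleotide, depending on the
    state space) per unit time."""
    pi = np.asarray(pi, dtype=float)
    S = np.asarray(S, dtype=float)
    n = pi.shape[0]
    if S.shape != (n, n):
        raise ValueError(f"dimension mismatch: pi has {n} states, S is {S.shape}")
    if scale_unit not in ("per-site", "per-dinucleotide"):
        raise ValueError(f"unknown scale unit {scale_unit!r}")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise ValueError(f"frequencies sum to {pi.sum()}, not 1")
    if (pi < 0).any():
        raise ValueError("negative frequencies")
    off = ~np.eye(n, dtype=bool)
    if not np.allclose(S, S.T, atol=1e-12):
        raise ValueError("exchangeability matrix is not symmetric")
    if (S[off] < 0).any():
        raise ValueError("negative exchangeabilities")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise ValueError("rate matrix has zero total rate")
    return Q / mu


class SubstitutionModel:
    """A named, parameterized reversible substitution model.

    Holds the equilibrium frequencies ``pi``, the symmetric exchangeability
    matrix ``S`` and the scaled rate matrix ``Q``, plus optional discrete-
    Gamma rate heterogeneity.  Transition matrices ``P(t) = exp(Q t)`` are
    computed through a cached symmetric eigendecomposition, which is exact
    for reversible matrices and stable even for the huge exchangeabilities
    used when projecting 7-state models to 16 states.
    """

    def __init__(
        self,
        name: str,
        pi: np.ndarray,
        S: np.ndarray,
        *,
        gamma_shape: float | None = None,
        n_gamma_cats: int = 4,
        class_label: str = "custom",
        free_param_count: int = 0,
        rescale: bool = True,
        Q: np.ndarray | None = None,
    ):
        self.name = name
        self.pi = np.asarray(pi, dtype=float)
        self.S = np.asarray(S, dtype=float)
        self.n_states = self.pi.shape[0]
        self.gamma_shape = gamma_shape
        self.n_gamma_cats = n_gamma_cats
        self.class_label = class_label
        self.free_param_count = free_param_count
        if Q is not None:
            self.Q = np.asarray(Q, dtype=float)
        elif rescale:
            unit = "per-site" if self.n_states == 4 else "per-dinucleotide"
            self.Q = build_rate_matrix(self.pi, self.S, unit)
        else:
            Q = self.S * self.pi[None, :]
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            self.Q = Q
        self._eig = None

    @property
    def expected_rate(self) -> float:
        """Expected substitutions per character per unit time."""
        return float(-(self.pi * np.diag(self.Q)).sum())

    def gamma_rates(self) -> GammaRates:
        if self.gamma_shape is None:
            return GammaRates(float("inf"), np.array([1.0]), np.array([1.0]))
        return discretize_gamma(self.gamma_shape, self.n_gamma_cats)

    def _decompose(self):
        if self._eig is None:
            sq = np.sqrt(self.pi)
            A = self.Q * (sq[:, None] / sq[None, :])
            A = (A + A.T) / 2.0
            w, V = np.linalg.eigh(A)
            self._eig = (w, V / sq[:, None], V.T * sq[None, :])
        return self._eig

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q t rate); rows sum to one."""
        if t < 0:
            raise ValueError(f"branch length must be >= 0, got {t}")
        w, U1, U2 = self._decompose()
        P = (U1 * np.exp(w * t * rate)) @ U2
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def with_gamma(self, shape: float | None, n_cats: int = 4) -> "SubstitutionModel":
        m = SubstitutionModel(
            self.name,
            self.pi,
            self.S,
            gamma_shape=shape,
            n_gamma_cats=n_cats,
            class_label=self.class_label,
            free_param_count=self.free_param_count,
            Q=self.Q,
        )
        return m

    def __repr__(self):  # pragma: no cover
        g = f"+G(shape={self.gamma_shape:.3g})" if self.gamma_shape else ""
        return f"<SubstitutionModel {self.name}{g} states={self.n_states}>"


# ---------------------------------------------------------------------------
# building models from descriptors


def _frequencies_from_params(desc: ModelDescriptor, params: Mapping) -> np.ndarray:
    structure = desc.frequency_structure
    if structure == "stable_sets":
        ss = StableSetsParams(
            np.asarray(params["nuc_pi"], dtype=float),
            float(params["alpha"]),
            float(params["beta"]),
        )
        pi, _ = stable_sets_frequencies(ss)
        return pi
    try:
        pi = np.asarray(params["pi"], dtype=float)
    except KeyError:
        raise ValueError(f"model {desc.name} requires a 'pi' frequency vector") from None
    if pi.shape != (desc.n_states,):
        raise ValueError(
            f"model {desc.name} needs {desc.n_states} frequencies, got {pi.shape}"
        )
    if abs(pi.sum() - 1.0) > 1e-8 or (pi <= 0).any():
        raise ValueError("frequencies must be positive and sum to 1")
    if structure == "strand_symmetric":
        if not np.allclose(pi, pi[STRAND_SWAP7], atol=1e-8):
            raise ValueError(
                f"model {desc.name} requires strand-symmetric frequencies "
                f"(pi[XY] == pi[YX])"
            )
    elif structure == "pooled_mismatch":
        mm = pi[MISMATCH16_INDICES]
        if not np.allclose(mm, mm.mean(), atol=1e-8):
            raise ValueError(
                f"model {desc.name} requires the ten mismatch frequencies to be "
                f"equal shares of one mismatch mass"
            )
    return pi


def _exchangeability_matrix(desc: ModelDescriptor, rates: Mapping[str, float]) -> np.ndarray:
    known = set(desc.rate_class_names)
    unknown = set(rates) - known
    if unknown:
        raise ValueError(
            f"model {desc.name}: unknown rate classes {sorted(unknown)}; "
            f"expected among {sorted(known)}"
        )
    S = np.zeros((desc.n_states, desc.n_states))
    for (i, j), cls in desc.exchangeability.items():
        val = float(rates.get(cls, 1.0))
        if val < 0:
            raise ValueError(f"rate class {cls} must be >= 0, got {val}")
        S[i, j] = S[j, i] = val
    return S


def build_model(name: str, params: Mapping) -> SubstitutionModel:
    """Instantiate a registered foundation model.

    ``params`` carries the frequency specification (``pi`` for most models;
    ``nuc_pi``/``alpha``/``beta`` for Stable Sets models), a ``rates``
    mapping of exchangeability-class values (missing classes default to 1;
    for HKY the shortcut ``kappa`` sets the transition/transversion ratio)
    and optionally ``gamma_shape`` / ``n_gamma_cats``.
    """
    desc = descriptor(name)
    params = dict(params)
    rates = dict(params.get("rates", {}))
    if "kappa" in params:
        if name not in ("HKY",):
            raise ValueError("'kappa' shortcut only applies to HKY")
        rates = {"ts": float(params["kappa"]), "tv": 1.0}
    pi = _frequencies_from_params(desc, params)
    S = _exchangeability_matrix(desc, rates)
    return SubstitutionModel(
        name,
        pi,
        S,
        gamma_shape=params.get("gamma_shape"),
        n_gamma_cats=int(params.get("n_gamma_cats", 4)),
        class_label=desc.class_label,
        free_param_count=desc.free_param_count,
    )


# ---------------------------------------------------------------------------
# empirical frequencies


def _counts(obs: np.ndarray, n_states: int) -> np.ndarray:
    flat = obs[obs >= 0]
    if flat.size == 0:
        raise ValueError("no unambiguous observations; cannot count frequencies")
    return np.bincount(flat, minlength=n_states).astype(float)


def _pseudo(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    out = counts.copy()
    out[out == 0] += pseudocount
    return out


def empirical_frequencies(
    enc,
    space: int,
    region: str = "auto",
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Normalized empirical state counts over unambiguous observations.

    ``region`` selects which observations feed a 4-state count: ``loop``,
    ``stem`` (the nucleotides inside paired columns), or ``all``; ``auto``
    means loop.  Zero cells receive ``pseudocount`` before normalization so
    that no observable state gets zero equilibrium frequency.
    """
    if space == 4:
        region = "loop" if region == "auto" else region
        if region == "loop":
            obs = enc.loop_obs
        elif region == "stem":
            obs = enc.stem_nuc
        elif region == "all":
            obs = np.concatenate([enc.loop_obs, enc.stem_nuc], axis=1)
        else:
            raise ValueError(f"unknown region {region!r}")
        counts = _counts(obs, 4)
    elif space == 7:
        counts = _counts(enc.stem7, 7)
    elif space == 16:
        counts = _counts(enc.stem16, 16)
    else:
        raise ValueError(f"state space must be 4, 7 or 16, got {space}")
    counts = _pseudo(counts, pseudocount)
    return counts / counts.sum()


def _stable_sets_initial(enc, pseudocount: float) -> dict:
    """Empirical nucleotide frequencies plus moment-matched alpha/beta starts."""
    nuc_counts = _pseudo(_counts(enc.stem_nuc, 4), pseudocount)
    nuc_pi = nuc_counts / nuc_counts.sum()
    pair_counts = _pseudo(_counts(enc.stem16, 16), pseudocount)
    pair_freq = pair_counts / pair_counts.sum()
    indep = np.outer(nuc_pi, nuc_pi).ravel()
    wc = [DINUC16.index(d) for d in WATSON_CRICK]
    wb = [DINUC16.index(d) for d in WOBBLE]
    mm = [i for i in range(16) if i not in wc and i not in wb]
    base = pair_freq[mm].sum() / indep[mm].sum()
    alpha0 = max(pair_freq[wc].sum() / indep[wc].sum() / base, 1e-3)
    beta0 = max(pair_freq[wb].sum() / indep[wb].sum() / base, 1e-3)
    return {"nuc_pi": nuc_pi, "alpha": float(alpha0), "beta": float(beta0)}


def empirical_params(
    name: str, enc, region: str = "auto", pseudocount: float = 0.5
) -> dict:
    """Frequency parameters for ``build_model`` taken from empirical counts,
    respecting the model's frequency structure (counts are pooled over the
    structure's equivalence classes before normalization)."""
    desc = descriptor(name)
    structure = desc.frequency_structure
    if structure == "stable_sets":
        return _stable_sets_initial(enc, pseudocount)
    if desc.n_states == 4:
        return {"pi": empirical_frequencies(enc, 4, region, pseudocount)}
    if structure == "free":
        return {"pi": empirical_frequencies(enc, desc.n_states, region, pseudocount)}
    if structure == "strand_symmetric":
        counts = _counts(enc.stem7, 7)
        pooled = np.zeros(7)
        for i in range(7):
            pooled[i] = (counts[i] + counts[STRAND_SWAP7[i]]) / 2.0
        pooled = _pseudo(pooled, pseudocount / 2.0)
        return {"pi": pooled / pooled.sum()}
    if structure == "pooled_mismatch":
        counts16 = _counts(enc.stem16, 16)
        pooled = counts16.copy()
        mm_mass = counts16[MISMATCH16_INDICES].sum()
        pooled[MISMATCH16_INDICES] = mm_mass / 10.0
        pooled = _pseudo(pooled, pseudocount / 10.0)
        return {"pi": pooled / pooled.sum()}
    raise AssertionError(structure)  # pragma: no cover
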