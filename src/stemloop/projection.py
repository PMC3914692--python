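"""State-space projections that make 4-, 7- and 16-state likelihoods
directly comparable.

Two constructions:

* **4 -> 16**: a nucleotide model applied independently to the two columns
  of every base pair is *exactly* a 16-state dinucleotide model whose
  single-position rates copy the 4-state rates, whose double-position
  rates are zero, and whose equilibrium is the outer product of the
  nucleotide frequencies.  Likelihoods of 4-state and 16-state models are
  therefore directly comparable with no adjustment.

* **7 -> 16**: a 7-state model determines a 16-state model up to (a) how
  the pooled mismatch frequency mass is shared among the ten mismatch
  dinucleotides and (b) the exchangeability ``sigma`` among mismatches.
  In the limit of infinite ``sigma`` the mismatches become statistically
  indistinguishable and the 16-state log-likelihood equals the 7-state
  log-likelihood plus an additive correction: for every unambiguously
  observed mismatch at a leaf, the log of that mismatch's share of the
  pooled mismatch mass (log 1/10 under equal shares; the empirical share
  otherwise, at a cost of 9 extra free parameters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._states import (
    COLLAPSE_16_TO_7,
    DINUC16,
    MISMATCH16_INDICES,
    MM7,
)
from .models import SubstitutionModel
from .structure import EncodedPartition

__all__ = [
    "CorrectionResult",
    "project_4_to_16",
    "project_7_to_16",
    "correction_7_to_16",
    "comparable_aicc",
    "best_corrected_aicc",
]

#: finite stand-in for the infinite mismatch exchangeability; large enough
#: that mismatches equilibrate instantaneously on any branch of interest
LARGE_SIGMA = 1e7


def project_4_to_16(model4: SubstitutionModel) -> SubstitutionModel:
    """Product construction: the 16-state model equivalent to applying
    ``model4`` independently to both positions of a pair."""
    if model4.n_states != 4:
        raise ValueError("project_4_to_16 requires a 4-state model")
    Q4 = model4.Q
    pi16 = np.outer(model4.pi, model4.pi).ravel()
    Q16 = np.zeros((16, 16))
    for x in range(4):
        for y in range(4):
            i = 4 * x + y
            for z in range(4):
                if z != y:  # second position changes
                    Q16[i, 4 * x + z] = Q4[y, z]
                if z != x:  # first position changes
                    Q16[i, 4 * z + y] = Q4[x, z]
    np.fill_diagonal(Q16, -Q16.sum(axis=1))
    S16 = np.zeros((16, 16))
    off = ~np.eye(16, dtype=bool)
    S16[off] = Q16[off] / pi16[None, :].repeat(16, axis=0)[off]
    return SubstitutionModel(
        f"proj16({model4.name})",
        pi16,
        S16,
        gamma_shape=model4.gamma_shape,
        n_gamma_cats=model4.n_gamma_cats,
        class_label="projected",
        free_param_count=model4.free_param_count,
        Q=Q16,
    )


def project_7_to_16(
    model7: SubstitutionModel,
    mismatch_freqs: np.ndarray,
    sigma: float = LARGE_SIGMA,
) -> SubstitutionModel:
    """Embed a 7-state model in the 16-state space.

    ``mismatch_freqs`` assigns the ten mismatch dinucleotides (in 16-state
    order) frequencies summing to the 7-state mismatch frequency.  Rates
    between canonical pairs are copied; the rate from a canonical pair
    into a *specific* mismatch apportions the 7-state into-mismatch rate
    by that mismatch's share of the pooled mass; rates among mismatches
    are ``sigma`` times the target frequency.  ``sigma=inf`` is replaced
    by the documented large finite value ``LARGE_SIGMA``.
    """
    if model7.n_states != 7:
        raise ValueError("project_7_to_16 requires a 7-state model")
    f = np.asarray(mismatch_freqs, dtype=float)
    if f.shape != (10,):
        raise ValueError("mismatch_freqs must have length 10")
    pi_mm = model7.pi[MM7]
    if abs(f.sum() - pi_mm) > 1e-8:
        raise ValueError(
            f"mismatch frequencies sum to {f.sum():.6g} but the 7-state "
            f"mismatch frequency is {pi_mm:.6g}"
        )
    if (f <= 0).any():
        raise ValueError("mismatch frequencies must be positive")
    if np.isinf(sigma):
        sigma = LARGE_SIGMA
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    pi16 = np.empty(16)
    mm_pos = {int(g): k for k, g in enumerate(MISMATCH16_INDICES)}
    for i in range(16):
        c = COLLAPSE_16_TO_7[i]
        pi16[i] = f[mm_pos[i]] if c == MM7 else model7.pi[c]

    Q7 = model7.Q
    Q16 = np.zeros((16, 16))
    for i in range(16):
        ci = COLLAPSE_16_TO_7[i]
        for j in range(16):
            if i == j:
                continue
            cj = COLLAPSE_16_TO_7[j]
            if ci != MM7 and cj != MM7:
                if ci != cj:
                    Q16[i, j] = Q7[ci, cj]
            elif ci != MM7:  # canonical -> specific mismatch
                Q16[i, j] = Q7[ci, MM7] * pi16[j] / pi_mm
            elif cj != MM7:  # mismatch -> canonical
                Q16[i, j] = Q7[MM7, cj]
            else:  # mismatch <-> mismatch
                Q16[i, j] = sigma * pi16[j]
    np.fill_diagonal(Q16, -Q16.sum(axis=1))
    S16 = np.zeros((16, 16))
    off = ~np.eye(16, dtype=bool)
    S16[off] = (Q16 / pi16[None, :])[off]
    return SubstitutionModel(
        f"proj16({model7.name})",
        pi16,
        S16,
        gamma_shape=model7.gamma_shape,
        n_gamma_cats=model7.n_gamma_cats,
        class_label="projected",
        free_param_count=model7.free_param_count,
        Q=Q16,
    )


@dataclass
class CorrectionResult:
    """Additive log-likelihood adjustment projecting a 7-state fit into the
    16-state space, plus the parameter-count cost of the chosen mismatch
    frequency scheme."""

    delta_lnL: float
    extra_k: int
    mode: str
    per_taxon_site_terms: pd.DataFrame | None = None

    def to_tsv(self, path):
        if self.per_taxon_site_terms is None:
            raise ValueError("no per-observation breakdown was requested")
        self.per_taxon_site_terms.to_csv(path, sep="\t", index=False)


def correction_7_to_16(
    enc: EncodedPartition, mode: str = "equal", breakdown: bool = False
) -> CorrectionResult:
    """Sum of log frequency ratios (16-state over pooled 7-state) across
    all leaf pair observations.

    Match states contribute ratio 1 (log 0); an unambiguous mismatch
    contributes ``log 1/10`` under equal shares, or the log of its
    empirical share among all observed mismatches under empirical mode
    (falling back to equal mode with a warning if no mismatch was
    observed).  Ambiguous observations contribute nothing.
    """
    if mode not in ("equal", "empirical"):
        raise ValueError(f"mode must be 'equal' or 'empirical', got {mode!r}")
    is_mm = enc.stem7 == MM7  # implies unambiguous (ambiguous is -1)
    m = int(is_mm.sum())
    if mode == "empirical" and m == 0:
        warnings.warn(
            "no mismatches observed; empirical correction falls back to "
            "equal mismatch frequencies"
        )
        mode = "equal"
    extra_k = 9 if mode == "empirical" else 0
    if mode == "equal":
        term_of = np.full(16, np.log(0.1))
    else:
        counts = np.bincount(enc.stem16[is_mm].astype(int), minlength=16).astype(float)
        shares = np.zeros(16)
        observed = counts > 0
        shares[observed] = counts[observed] / m
        with np.errstate(divide="ignore"):
            term_of = np.where(observed, np.log(np.where(observed, shares, 1.0)), 0.0)
    delta = float(term_of[enc.stem16[is_mm].astype(int)].sum()) if m else 0.0
    frame = None
    if breakdown:
        rows = []
        taxon_idx, pair_idx = np.nonzero(is_mm)
        for ti, pi_ in zip(taxon_idx, pair_idx):
            code = int(enc.stem16[ti, pi_])
            rows.append(
                {
                    "taxon": enc.taxa[ti],
                    "pair_index": int(pi_),
                    "dinucleotide": DINUC16[code],
                    "term": float(term_of[code]),
                }
            )
        frame = pd.DataFrame(rows, columns=["taxon", "pair_index", "dinucleotide", "term"])
    return CorrectionResult(delta, extra_k, mode, frame)


def comparable_aicc(fit, corr: CorrectionResult | None = None) -> float:
    """AICc on the common 16-state-projected scale.

    4-state and 16-state fits pass through unchanged; a 7-state stem fit
    requires a correction.
    """
    from .selection import aicc

    stem = fit.mixture.stem_model if fit.mixture is not None else None
    is7 = stem is not None and stem.n_states == 7
    if is7 and corr is None:
        raise ValueError("a 7-state stem fit requires a likelihood correction")
    if corr is None:
        return aicc(fit.lnL, fit.k, fit.n)
    return aicc(fit.lnL + corr.delta_lnL, fit.k + corr.extra_k, fit.n)


def best_corrected_aicc(fit, enc: EncodedPartition) -> tuple[float, str]:
    """Evaluate both correction modes for a 7-state fit and keep the one
    with the lower AICc (ties resolved toward the unparameterized equal
    mode)."""
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for mode in ("equal", "empirical"):
            corr = correction_7_to_16(enc, mode)
            results.append((comparable_aicc(fit, corr), corr.mode))
    results.sort(key=lambda r: (r[0], r[1] != "equal"))
    return results[0]
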