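"""Candidate enumeration, AICc, and the model-selection sweep.

The candidate space pairs a loop model (HKY+G or GTR+G) with one of 34
stem options (the two nucleotide models, or any of the 16 dinucleotide
foundation models with or without Gamma rates), yielding 68 partitioned
mixtures, plus two unpartitioned single-model candidates: 70 in total.
Every candidate is fitted by ML on the fixed tree; 7-state candidates are
made comparable through the 16-state projection correction, scoring both
the equal and the empirical mismatch-frequency variants and keeping the
better one.  Candidates are ranked by AICc.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models as _models
from .likelihood import MixtureSpec, fit_ml
from .projection import best_corrected_aicc
from .structure import StructuredAlignment, encode
from .trees import PhyloTree

__all__ = [
    "CandidateSpec",
    "SelectionReport",
    "enumerate_candidates",
    "sample_size",
    "aicc",
    "select",
]

#: a candidate is just a names-only mixture specification
CandidateSpec = MixtureSpec

LOOP_MODELS = ("HKY+G", "GTR+G")
DINUC_MODELS = (
    "16A", "16B", "16C", "16D", "16E", "16F", "16I", "16J", "16K",
    "7A", "7B", "7C", "7D", "7E", "7F", "7G",
)


def stem_options() -> list[str]:
    """The 34 stem choices: 2 nucleotide models + 16 dinucleotide models
    with and without Gamma rates."""
    out = list(LOOP_MODELS)
    for m in DINUC_MODELS:
        out.extend([m, m + "+G"])
    return out


def enumerate_candidates() -> list[CandidateSpec]:
    """All 70 candidates: 68 loop x stem mixtures plus 2 unpartitioned
    single nucleotide models."""
    cands = [CandidateSpec(loop, None, partitioned=False) for loop in LOOP_MODELS]
    for loop in LOOP_MODELS:
        for stem in stem_options():
            cands.append(CandidateSpec(loop, stem, partitioned=True))
    return cands


def sample_size(aln: StructuredAlignment) -> int:
    """Alignment characters, each base pair counting as one character."""
    n = len(aln.mask.loop_columns) + len(aln.mask.pairs)
    if n == 0:
        raise ValueError("empty alignment: no columns to count")
    return n


def aicc(lnL: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined: sample size n={n} must exceed k+1={k + 1}"
        )
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class SelectionReport:
    """Ranked results of one model-selection sweep."""

    table: pd.DataFrame
    best: CandidateSpec | None

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_json(self, path=None):
        payload = {
            "best": None if self.best is None else self.best.name,
            "rows": json.loads(self.table.to_json(orient="records")),
        }
        if path is None:
            return json.dumps(payload, indent=2)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _candidate_class(spec: CandidateSpec) -> str:
    if spec.stem_name is None or spec.stem_states == 4:
        return "DNA"
    return _models.descriptor(spec.stem_base).class_label


def _candidate_seed(base_seed: int, name: str) -> int:
    return (base_seed ^ zlib.crc32(name.encode())) % (2**31 - 1)


def select(
    aln: StructuredAlignment,
    tree: PhyloTree,
    candidates: list[CandidateSpec] | None = None,
    optimize_branch_lengths: bool = False,
    seed: int = 0,
    n_starts: int = 3,
    n_gamma_cats: int = 4,
) -> SelectionReport:
    """Fit every candidate, apply state-space corrections, rank by AICc.

    Individual fit failures are recorded per row and never abort the
    sweep.  Per-candidate seeds derive from ``seed`` and the candidate
    name, so results are order-independent and removing one candidate
    leaves the others' rows unchanged.
    """
    if candidates is None:
        candidates = enumerate_candidates()
    if not candidates:
        raise ValueError("no candidates to evaluate")
    enc = encode(aln)
    n = sample_size(aln)
    rows = []
    for spec in candidates:
        spec = CandidateSpec(
            spec.loop_name, spec.stem_name, spec.partitioned, n_gamma_cats
        )
        row = {
            "candidate": spec.name,
            "class": _candidate_class(spec),
            "lnL": np.nan,
            "correction": "none",
            "k": np.nan,
            "n": n,
            "aicc": np.nan,
            "converged": False,
            "error": "",
        }
        try:
            fit = fit_ml(
                tree,
                spec,
                enc,
                optimize_branch_lengths=optimize_branch_lengths,
                n_starts=n_starts,
                seed=_candidate_seed(seed, spec.name),
            )
            row["lnL"] = fit.lnL
            row["k"] = fit.k
            row["converged"] = fit.converged
            if spec.stem_states == 7:
                value, mode = best_corrected_aicc(fit, enc)
                row["aicc"] = value
                row["correction"] = mode
                if mode == "empirical":
                    row["k"] = fit.k + 9
            else:
                row["aicc"] = fit.aicc
        except Exception as exc:  # noqa: BLE001 - sweep must not die
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["aicc", "k", "candidate"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    finite = table["aicc"].notna()
    if finite.any():
        table["delta_aicc"] = table["aicc"] - table.loc[finite, "aicc"].min()
        best_name = table.loc[finite, "candidate"].iloc[0]
        best = next(
            s for s in candidates
            if CandidateSpec(s.loop_name, s.stem_name, s.partitioned, n_gamma_cats).name
            == best_name
        )
    else:
        table["delta_aicc"] = np.nan
        best = None
    return SelectionReport(table=table, best=best)
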