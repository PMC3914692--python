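"""Declarative descriptors for the 18 foundation substitution models.

Each model is a recipe, not a matrix: a frequency structure, a partition of
the off-diagonal state pairs into exchangeability equivalence classes, and a
flag saying whether substitutions that change both nucleotides of a pair at
once are permitted.  The likelihood engine instantiates a concrete
reversible rate matrix from a descriptor plus numeric parameter values.

The four model classes mirror how each family treats paired bases:

``DNA``
    HKY and GTR; nucleotides evolve independently, pairing is ignored.
``StablePairs``
    One free frequency per stable canonical pair, mismatches pooled into a
    single frequency mass (the seven 7-state models, and 16C which spreads
    the pooled mismatch mass equally over the ten mismatch dinucleotides).
``StableSets``
    16D/16E/16F; dinucleotide frequencies are products of single-nucleotide
    frequencies boosted by a Watson-Crick propensity ``alpha`` and a wobble
    propensity ``beta``.  Because rates are exchangeabilities times target
    frequencies, alpha and beta shape both the equilibrium and the flow.
``AllPairs``
    16A/16B/16I/16J/16K; every one of the 16 dinucleotides has its own
    free frequency.

Within the 7-state family, 7G (strand-symmetric frequencies, one rate for
single-position changes between canonical pairs and one rate in and out of
the mismatch state) is a restriction of both 7E (free frequencies) and 7F
(strand-symmetric frequencies with per-orbit rates).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from ._states import (
    CANONICAL_PAIRS,
    DINUC16,
    NUC,
    PAIR7,
    dinuc_hamming,
    is_transition,
)

FREQ_DF = {
    # number of free frequency-side parameters by structure (4/7/16-state)
    ("free", 4): 3,
    ("free", 7): 6,
    ("free", 16): 15,
    ("strand_symmetric", 7): 3,
    ("pooled_mismatch", 16): 6,
    ("stable_sets", 16): 5,  # 3 nucleotide frequencies + alpha + beta
}


@dataclass(frozen=True)
class ModelDescriptor:
    """Recipe for one foundation model.

    ``exchangeability`` maps an unordered state-index pair ``(i, j)`` with
    ``i < j`` to the name of its rate class; pairs absent from the mapping
    have instantaneous rate zero.
    """

    name: str
    n_states: int
    class_label: str
    frequency_structure: str
    allow_double: bool
    exchangeability: Mapping[tuple[int, int], str] = field(repr=False)

    @property
    def rate_class_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for key in sorted(self.exchangeability):
            seen.setdefault(self.exchangeability[key], None)
        return tuple(seen)

    @property
    def free_param_count(self) -> int:
        """Frequency df plus exchangeability df (one class absorbed by the
        overall rate scaling)."""
        return (
            FREQ_DF[(self.frequency_structure, self.n_states)]
            + len(self.rate_class_names)
            - 1
        )

    @property
    def state_names(self) -> tuple[str, ...]:
        if self.n_states == 4:
            return tuple(NUC)
        if self.n_states == 7:
            return PAIR7
        return DINUC16

    def to_yaml(self) -> str:
        names = self.state_names
        exch = {
            f"{names[i]}:{names[j]}": cls
            for (i, j), cls in sorted(self.exchangeability.items())
        }
        doc = {
            "name": self.name,
            "states": self.n_states,
            "class_label": self.class_label,
            "frequency_structure": self.frequency_structure,
            "allow_double": self.allow_double,
            "free_param_count": self.free_param_count,
            "exchangeability": exch,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelDescriptor":
        doc = yaml.safe_load(text)
        n = doc["states"]
        names = tuple(NUC) if n == 4 else (PAIR7 if n == 7 else DINUC16)
        index = {s: i for i, s in enumerate(names)}
        exch = {}
        for key, label in doc["exchangeability"].items():
            a, b = key.split(":")
            i, j = sorted((index[a], index[b]))
            exch[(i, j)] = label
        desc = cls(
            name=doc["name"],
            n_states=n,
            class_label=doc["class_label"],
            frequency_structure=doc["frequency_structure"],
            allow_double=doc["allow_double"],
            exchangeability=exch,
        )
        if "free_param_count" in doc and doc["free_param_count"] != desc.free_param_count:
            raise ValueError(
                f"descriptor {desc.name}: stored free_param_count "
                f"{doc['free_param_count']} != derived {desc.free_param_count}"
            )
        return desc


# ---------------------------------------------------------------------------
# edge classification helpers


def _edges(n: int):
    return itertools.combinations(range(n), 2)


def _edge_type7(i: int, j: int) -> str:
    """single / double (canonical-canonical) or mm (into the mismatch state)."""
    a, b = PAIR7[i], PAIR7[j]
    if "MM" in (a, b):
        return "mm"
    return "single" if dinuc_hamming(a, b) == 1 else "double"


def _strand_orbit7(i: int, j: int) -> tuple[int, int]:
    """Canonical representative of an edge under strand exchange X:Y -> Y:X."""
    from ._states import STRAND_SWAP7

    swapped = tuple(sorted((int(STRAND_SWAP7[i]), int(STRAND_SWAP7[j]))))
    return min((i, j), swapped)


def _changed_nucs(a: str, b: str) -> str:
    """Sorted pair of nucleotides exchanged by a single-position change."""
    pos = 0 if a[0] != b[0] else 1
    return "".join(sorted((a[pos], b[pos])))


# ---------------------------------------------------------------------------
# the 18 foundation models


def _dna(name: str, classes: str) -> ModelDescriptor:
    exch = {}
    for i, j in _edges(4):
        pair = "".join(sorted((NUC[i], NUC[j])))
        if classes == "gtr":
            exch[(i, j)] = f"s_{pair}"
        else:  # hky
            exch[(i, j)] = "ts" if is_transition(NUC[i], NUC[j]) else "tv"
    return ModelDescriptor(name, 4, "DNA", "free", False, exch)


def _seven(name, freq_structure, scheme, allow_double) -> ModelDescriptor:
    exch = {}
    for i, j in _edges(7):
        etype = _edge_type7(i, j)
        if etype == "double" and not allow_double:
            continue
        if scheme == "all_distinct":
            exch[(i, j)] = f"s_{PAIR7[i]}_{PAIR7[j]}"
        elif scheme == "strand_orbits":
            oi, oj = _strand_orbit7(i, j)
            exch[(i, j)] = f"s_{PAIR7[oi]}_{PAIR7[oj]}"
        elif scheme == "per_edge_singles_pooled_doubles":
            # singles and mismatch edges keep their own rate, all double
            # substitutions between canonical pairs share one rate
            if etype == "double":
                exch[(i, j)] = "double"
            else:
                exch[(i, j)] = f"s_{PAIR7[i]}_{PAIR7[j]}"
        elif scheme == "single_double_mm":
            exch[(i, j)] = etype
        elif scheme == "single_mm":
            exch[(i, j)] = etype  # doubles excluded above
        elif scheme == "orbit_single_mm":
            oi, oj = _strand_orbit7(i, j)
            exch[(i, j)] = f"s_{PAIR7[oi]}_{PAIR7[oj]}"
        else:  # pragma: no cover
            raise AssertionError(scheme)
    return ModelDescriptor(name, 7, "StablePairs", freq_structure, allow_double, exch)


def _sixteen(name, class_label, freq_structure, single_scheme, allow_double) -> ModelDescriptor:
    exch = {}
    for i, j in _edges(16):
        a, b = DINUC16[i], DINUC16[j]
        ham = dinuc_hamming(a, b)
        if ham == 2 and not allow_double:
            continue
        if single_scheme == "tillier":
            # single / double within the canonical set; pooled rates for
            # traffic touching the mismatch set (16C extends 7D this way)
            a_can = a in CANONICAL_PAIRS
            b_can = b in CANONICAL_PAIRS
            if a_can and b_can:
                exch[(i, j)] = "single" if ham == 1 else "double"
            elif a_can or b_can:
                exch[(i, j)] = "pair_mm"
            else:
                exch[(i, j)] = "mm_mm"
            continue
        if ham == 2:
            exch[(i, j)] = "double"
            continue
        nucs = _changed_nucs(a, b)
        if single_scheme == "gtr":
            exch[(i, j)] = f"s_{nucs}"
        elif single_scheme == "tstv":
            exch[(i, j)] = "ts" if is_transition(*nucs) else "tv"
        elif single_scheme == "one":
            exch[(i, j)] = "single"
        else:  # pragma: no cover
            raise AssertionError(single_scheme)
    return ModelDescriptor(name, 16, class_label, freq_structure, allow_double, exch)


def builtin_descriptors() -> dict[str, ModelDescriptor]:
    d = {}

    d["HKY"] = _dna("HKY", "hky")
    d["GTR"] = _dna("GTR", "gtr")

    d["7A"] = _seven("7A", "free", "all_distinct", True)
    d["7B"] = _seven("7B", "strand_symmetric", "strand_orbits", True)
    d["7C"] = _seven("7C", "free", "per_edge_singles_pooled_doubles", True)
    d["7D"] = _seven("7D", "free", "single_double_mm", True)
    d["7E"] = _seven("7E", "free", "single_mm", False)
    d["7F"] = _seven("7F", "strand_symmetric", "orbit_single_mm", False)
    d["7G"] = _seven("7G", "strand_symmetric", "single_mm", False)

    d["16A"] = _sixteen("16A", "AllPairs", "free", "gtr", False)
    d["16B"] = _sixteen("16B", "AllPairs", "free", "gtr", True)
    d["16I"] = _sixteen("16I", "AllPairs", "free", "one", False)
    d["16J"] = _sixteen("16J", "AllPairs", "free", "tstv", False)
    d["16K"] = _sixteen("16K", "AllPairs", "free", "tstv", True)

    d["16C"] = _sixteen("16C", "StablePairs", "pooled_mismatch", "tillier", True)

    d["16D"] = _sixteen("16D", "StableSets", "stable_sets", "tstv", True)
    d["16E"] = _sixteen("16E", "StableSets", "stable_sets", "tstv", False)
    d["16F"] = _sixteen("16F", "StableSets", "stable_sets", "one", False)

    return d


#: documented nesting relations (restricted -> general); used by property
#: tests asserting monotone maximized likelihoods.
NESTINGS = (
    ("HKY", "GTR"),
    ("7G", "7E"),
    ("7G", "7F"),
    ("7D", "7C"),
    ("7C", "7A"),
    ("7B", "7A"),
    ("16I", "16J"),
    ("16J", "16A"),
    ("16F", "16E"),
)
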