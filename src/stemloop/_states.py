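"""State-space conventions shared across the package.

Orderings are fixed and load-bearing: every frequency vector, rate matrix
and encoded observation uses them.

* nucleotides: ``A C G U`` (indices 0..3)
* 16-state dinucleotides: first-nucleotide-major, ``AA AC AG AU CA .. UU``
* 7-state pair alphabet: ``AU GU GC UA UG CG MM`` — the six stable
  canonical base pairs (Watson-Crick A:U/U:A and C:G/G:C plus the wobble
  G:U/U:G) followed by the single mismatch state that absorbs the ten
  remaining dinucleotides.
"""

from __future__ import annotations

import numpy as np

NUC = "ACGU"
NUC_INDEX = {c: i for i, c in enumerate(NUC)}

DINUC16 = tuple(a + b for a in NUC for b in NUC)
DINUC16_INDEX = {d: i for i, d in enumerate(DINUC16)}

CANONICAL_PAIRS = ("AU", "GU", "GC", "UA", "UG", "CG")
PAIR7 = CANONICAL_PAIRS + ("MM",)
PAIR7_INDEX = {p: i for i, p in enumerate(PAIR7)}
MM7 = PAIR7_INDEX["MM"]

MISMATCH_DINUCS = tuple(d for d in DINUC16 if d not in CANONICAL_PAIRS)
MISMATCH16_INDICES = np.array([DINUC16_INDEX[d] for d in MISMATCH_DINUCS])
CANONICAL16_INDICES = np.array([DINUC16_INDEX[d] for d in CANONICAL_PAIRS])

#: canonical 16 -> 7 collapse: six canonical dinucleotides map to their own
#: state, the ten mismatches map to MM.
COLLAPSE_16_TO_7 = np.array(
    [PAIR7_INDEX.get(d, MM7) for d in DINUC16], dtype=np.int8
)

#: strand exchange X:Y -> Y:X on the 7-state alphabet (MM is fixed).
STRAND_SWAP7 = np.array(
    [PAIR7_INDEX[p[::-1]] if p != "MM" else MM7 for p in PAIR7], dtype=np.int8
)

WATSON_CRICK = ("AU", "UA", "CG", "GC")
WOBBLE = ("GU", "UG")

TRANSITIONS = (frozenset("AG"), frozenset("CU"))


def is_transition(x: str, y: str) -> bool:
    return frozenset((x, y)) in TRANSITIONS


def dinuc_hamming(d1: str, d2: str) -> int:
    return (d1[0] != d2[0]) + (d1[1] != d2[1])
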