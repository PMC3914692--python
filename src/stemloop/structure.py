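"""Structure-annotated RNA alignments: parsing, partitioning, encoding.

An alignment plus a consensus secondary structure partitions columns into
*loop* sites (unpaired, evolving as independent nucleotides) and *stem*
column pairs (base-paired, evolving as dinucleotides).  Supported inputs:
Stockholm with a ``#=GC SS_cons`` line, FASTA with a sidecar dot-bracket
file, and a plain pair-list text format (one ``i j`` per line, 0-based).

Encoding maps leaf observations into three state spaces at once: the
4-state nucleotide space, the 16-state dinucleotide space (first-nucleotide
major: AA, AC, ..., UU) and the 7-state space [AU, GU, GC, UA, UG, CG, MM]
in which the ten mismatched dinucleotides collapse to the single MM state.
A dinucleotide containing a gap or N is fully ambiguous in both pair
spaces.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._states import COLLAPSE_16_TO_7, NUC_INDEX

__all__ = [
    "PairingMask",
    "StructuredAlignment",
    "EncodedPartition",
    "parse_dotbracket",
    "mask_to_dotbracket",
    "read_stockholm",
    "write_stockholm",
    "read_fasta_with_structure",
    "write_fasta_with_structure",
    "read_pairlist",
    "write_pairlist",
    "encode",
]

_OPEN = "(<[{"
_CLOSE = ")>]}"
_UNPAIRED = ".,_-:~"
_FAMILIES = list(zip(_OPEN, _CLOSE)) + [
    (chr(ord("A") + k), chr(ord("a") + k)) for k in range(26)
]


@dataclass(frozen=True)
class PairingMask:
    """Partition of alignment columns into base pairs and loop columns.

    Pairs are ordered by opening column; crossing pairs (pseudoknots) are
    permitted.  Every column belongs to exactly one pair or to the loop.
    """

    pairs: tuple[tuple[int, int], ...]
    loop_columns: tuple[int, ...]

    def __post_init__(self):
        seen = set()
        for i, j in self.pairs:
            if i >= j:
                raise ValueError(f"pair ({i}, {j}) must satisfy i < j")
            for c in (i, j):
                if c in seen:
                    raise ValueError(f"column {c} occurs in more than one pair")
                seen.add(c)
        for c in self.loop_columns:
            if c in seen:
                raise ValueError(f"column {c} is both paired and loop")
            seen.add(c)

    @property
    def n_columns(self) -> int:
        return 2 * len(self.pairs) + len(self.loop_columns)

    def validate_length(self, n_cols: int):
        expected = set(range(n_cols))
        have = set(self.loop_columns)
        for i, j in self.pairs:
            have.add(i)
            have.add(j)
        if have != expected:
            raise ValueError(
                f"mask covers columns {sorted(have)[:5]}... but alignment has "
                f"{n_cols} columns"
            )


def parse_dotbracket(db: str) -> PairingMask:
    """Bracket-match a dot-bracket string into a :class:`PairingMask`.

    Bracket families ``()``, ``<>``, ``[]``, ``{}`` and ``Aa``..``Zz`` are
    matched independently, so pseudoknots expressed with distinct families
    are accepted.  Characters in ``. , _ - : ~`` are unpaired.
    """
    stacks: dict[str, list[int]] = {}
    open_of = {o: o for o, _ in _FAMILIES}
    close_of = {c: o for o, c in _FAMILIES}
    pairs = []
    loops = []
    for col, ch in enumerate(db):
        if ch in _UNPAIRED:
            loops.append(col)
        elif ch in open_of:
            stacks.setdefault(ch, []).append(col)
        elif ch in close_of:
            fam = close_of[ch]
            stack = stacks.get(fam, [])
            if not stack:
                raise ValueError(
                    f"unbalanced structure: unmatched {ch!r} at column {col}"
                )
            pairs.append((stack.pop(), col))
        else:
            raise ValueError(
                f"unknown structure character {ch!r} at column {col}"
            )
    for fam, stack in stacks.items():
        if stack:
            raise ValueError(
                f"unbalanced structure: unclosed {fam!r} at column {stack[-1]}"
            )
    pairs.sort()
    return PairingMask(tuple(pairs), tuple(loops))


def mask_to_dotbracket(mask: PairingMask, n_cols: int | None = None) -> str:
    """Render a mask as dot-bracket, assigning crossing pairs to successive
    bracket families so the string re-parses to the same mask."""
    n_cols = mask.n_columns if n_cols is None else n_cols
    out = ["."] * n_cols
    families: list[list[tuple[int, int]]] = []
    for i, j in sorted(mask.pairs):
        placed = False
        for fam_idx, fam_pairs in enumerate(families):
            if all(not (a < i < b < j or i < a < j < b) for a, b in fam_pairs):
                fam_pairs.append((i, j))
                o, c = _FAMILIES[fam_idx]
                out[i], out[j] = o, c
                placed = True
                break
        if not placed:
            families.append([(i, j)])
            o, c = _FAMILIES[len(families) - 1]
            out[i], out[j] = o, c
    return "".join(out)


@dataclass
class StructuredAlignment:
    """Aligned RNA sequences plus the stem/loop pairing mask.

    Rows are normalized on construction: uppercased, T replaced by U.
    """

    taxa: list[str]
    rows: list[str]
    mask: PairingMask

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa and rows differ in length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa names must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        self.rows = [r.upper().replace("T", "U") for r in self.rows]
        if self.rows:
            self.mask.validate_length(len(self.rows[0]))

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)


# ---------------------------------------------------------------------------
# readers / writers


def read_stockholm(path) -> StructuredAlignment:
    """Read a Stockholm alignment whose ``#=GC SS_cons`` line carries the
    consensus structure."""
    aln = AlignIO.read(str(path), "stockholm")
    ss = aln.column_annotations.get("secondary_structure")
    if ss is None:
        raise ValueError(f"{path}: no #=GC SS_cons line")
    if len(ss) != aln.get_alignment_length():
        raise ValueError(
            f"{path}: SS_cons length {len(ss)} != alignment length "
            f"{aln.get_alignment_length()}"
        )
    return StructuredAlignment(
        taxa=[rec.id for rec in aln],
        rows=[str(rec.seq) for rec in aln],
        mask=parse_dotbracket(ss),
    )


def write_stockholm(aln: StructuredAlignment, path):
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=name, description="") for name, row in zip(aln.taxa, aln.rows)]
    )
    msa.column_annotations["secondary_structure"] = mask_to_dotbracket(
        aln.mask, aln.n_columns
    )
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, "stockholm")


def _read_fasta(path) -> tuple[list[str], list[str]]:
    aln = AlignIO.read(str(path), "fasta")
    return [rec.id for rec in aln], [str(rec.seq) for rec in aln]


def read_fasta_with_structure(fasta_path, structure_path) -> StructuredAlignment:
    """FASTA alignment plus a sidecar file holding one dot-bracket string
    (an optional ``>`` header line is skipped)."""
    taxa, rows = _read_fasta(fasta_path)
    lines = [
        ln.strip()
        for ln in Path(structure_path).read_text().splitlines()
        if ln.strip() and not ln.startswith(">")
    ]
    if len(lines) != 1:
        raise ValueError(f"{structure_path}: expected exactly one structure line")
    return StructuredAlignment(taxa, rows, parse_dotbracket(lines[0]))


def write_fasta_with_structure(aln: StructuredAlignment, fasta_path, structure_path):
    with open(fasta_path, "w") as fh:
        for name, row in zip(aln.taxa, aln.rows):
            fh.write(f">{name}\n{row}\n")
    Path(structure_path).write_text(mask_to_dotbracket(aln.mask, aln.n_columns) + "\n")


def read_pairlist(fasta_path, pairs_path) -> StructuredAlignment:
    """FASTA alignment plus a pair-list file: one ``i j`` per line, 0-based
    column indices; unlisted columns are loop columns."""
    taxa, rows = _read_fasta(fasta_path)
    n_cols = len(rows[0])
    pairs = []
    for ln in Path(pairs_path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        i, j = (int(x) for x in ln.split())
        if not (0 <= i < n_cols and 0 <= j < n_cols):
            raise ValueError(f"{pairs_path}: pair ({i}, {j}) outside alignment")
        pairs.append((min(i, j), max(i, j)))
    pairs.sort()
    paired = {c for p in pairs for c in p}
    loops = tuple(c for c in range(n_cols) if c not in paired)
    return StructuredAlignment(taxa, rows, PairingMask(tuple(pairs), loops))


def write_pairlist(aln: StructuredAlignment, fasta_path, pairs_path):
    with open(fasta_path, "w") as fh:
        for name, row in zip(aln.taxa, aln.rows):
            fh.write(f">{name}\n{row}\n")
    with open(pairs_path, "w") as fh:
        for i, j in aln.mask.pairs:
            fh.write(f"{i} {j}\n")


# ---------------------------------------------------------------------------
# encoding


@dataclass
class EncodedPartition:
    """Leaf observations of one structured alignment in all state spaces.

    Codes are state indices; ``-1`` marks a fully ambiguous observation
    (gap, N or any other degenerate symbol).  ``stem16`` retains the raw
    dinucleotide identity needed by the 7-to-16 state likelihood
    correction; ``stem7`` is its canonical collapse.
    """

    taxa: list[str]
    loop_obs: np.ndarray  # (n_taxa, n_loop) int8
    stem16: np.ndarray  # (n_taxa, n_pairs) int8
    stem7: np.ndarray  # (n_taxa, n_pairs) int8
    stem_nuc: np.ndarray  # (n_taxa, 2 * n_pairs) int8
    loop_columns: tuple[int, ...]
    pairs: tuple[tuple[int, int], ...]
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_loop(self) -> int:
        return self.loop_obs.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.stem16.shape[1]

    def compressed(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Collapse identical observation columns; returns (patterns with
        shape (n_taxa, n_patterns), multiplicity weights).  Expanding the
        weights reproduces the uncompressed per-column likelihood sum."""
        if which not in self._cache:
            obs = {
                "loop": self.loop_obs,
                "stem16": self.stem16,
                "stem7": self.stem7,
                "stem_nuc": self.stem_nuc,
                "all_nuc": np.concatenate([self.loop_obs, self.stem_nuc], axis=1),
            }[which]
            if obs.shape[1] == 0:
                self._cache[which] = (obs, np.zeros(0))
            else:
                patterns, counts = np.unique(obs, axis=1, return_counts=True)
                self._cache[which] = (patterns, counts.astype(float))
        return self._cache[which]

    # spec-facing aliases
    @property
    def loop_patterns(self):
        return self.compressed("loop")[0]

    @property
    def stem_patterns(self):
        return self.compressed("stem16")[0]

    @property
    def pattern_weights(self):
        return {
            "loop": self.compressed("loop")[1],
            "stem": self.compressed("stem16")[1],
        }


def _codes(row: str) -> np.ndarray:
    return np.array([NUC_INDEX.get(ch, -1) for ch in row], dtype=np.int8)


def encode(aln: StructuredAlignment) -> EncodedPartition:
    """Encode leaf observations in the 4-, 7- and 16-state spaces."""
    codes = np.stack([_codes(row) for row in aln.rows]) if aln.n_taxa else np.zeros((0, 0), np.int8)
    loop_cols = list(aln.mask.loop_columns)
    loop_obs = codes[:, loop_cols] if loop_cols else np.zeros((aln.n_taxa, 0), np.int8)
    pairs = aln.mask.pairs
    n_pairs = len(pairs)
    stem16 = np.full((aln.n_taxa, n_pairs), -1, dtype=np.int8)
    stem_nuc = np.full((aln.n_taxa, 2 * n_pairs), -1, dtype=np.int8)
    for k, (i, j) in enumerate(pairs):
        a = codes[:, i]
        b = codes[:, j]
        ok = (a >= 0) & (b >= 0)
        stem16[ok, k] = 4 * a[ok] + b[ok]
        # a pair with any degenerate position is fully ambiguous in every
        # space, including the nucleotide view of stems: all stem scorings
        # must condition on the same data for likelihoods to be comparable
        stem_nuc[ok, 2 * k] = a[ok]
        stem_nuc[ok, 2 * k + 1] = b[ok]
    stem7 = np.where(stem16 >= 0, COLLAPSE_16_TO_7[np.clip(stem16, 0, 15)], -1).astype(np.int8)
    return EncodedPartition(
        taxa=list(aln.taxa),
        loop_obs=loop_obs.astype(np.int8),
        stem16=stem16,
        stem7=stem7,
        stem_nuc=stem_nuc,
        loop_columns=tuple(loop_cols),
        pairs=tuple(pairs),
    )
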