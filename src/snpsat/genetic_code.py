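"""The standard genetic code and the five-way physicochemical residue grouping.

The code table (NCBI translation table 1: 61 sense codons, 3 stop codons)
is packaged as a plain-text TSV so it can be inspected and diffed; it is
loaded once at import.  Residues are one-letter symbols; the stop signal
is the distinguished sentinel ``"*"``, which is never a member of the
20-amino-acid set.

The grouping partitions the 20 amino acids into five physicochemical
classes (positively charged, negatively charged, polar, special,
hydrophobic), with stop codons forming a sixth pseudo-group.  Under the
standard code the per-group codon counts are 10 / 4 / 14 / 10 / 23 / 3.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping

STOP = "*"

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_BASES = frozenset("ACGT")


class ResidueGroup(str, Enum):
    """Physicochemical class of a residue symbol."""

    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    POLAR = "POLAR"
    SPECIAL = "SPECIAL"
    HYDROPHOBIC = "HYDROPHOBIC"
    STOP = "STOP"

    def __str__(self) -> str:  # tidy TSV / CLI rendering
        return self.value


#: Charged residues form two groups here; some aggregate views merge them.
CHARGED_GROUPS = frozenset({ResidueGroup.POSITIVE, ResidueGroup.NEGATIVE})


class InvalidAlphabetError(ValueError):
    """A nucleotide outside A/C/G/T (or U) was encountered."""

    def __init__(self, char: str, position: int):
        self.char = char
        self.position = position
        super().__init__(
            f"invalid nucleotide {char!r} at position {position} "
            "(expected A, C, G, T or U)"
        )


class InvalidSymbolError(ValueError):
    """A residue symbol outside the 20 amino acids + stop sentinel."""

    def __init__(self, symbol: object):
        super().__init__(
            f"unknown residue symbol {symbol!r} "
            "(expected a one-letter amino-acid code or '*')"
        )


@dataclass(frozen=True)
class GeneticCodeTable:
    """Codon -> residue-symbol association for the standard code.

    Invariants (checked on construction): 64 codons, 61 sense + 3 stop
    (TAA, TAG, TGA), every amino acid represented, ATG -> Met.
    """

    codon_to_symbol: Mapping[str, str]
    three_letter: Mapping[str, str] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        codons = set(self.codon_to_symbol)
        if len(codons) != 64:
            raise ValueError(f"expected 64 codons, got {len(codons)}")
        stops = {c for c, s in self.codon_to_symbol.items() if s == STOP}
        if stops != {"TAA", "TAG", "TGA"}:
            raise ValueError(f"stop codons must be TAA/TAG/TGA, got {sorted(stops)}")
        symbols = set(self.codon_to_symbol.values()) - {STOP}
        if symbols != set(AMINO_ACIDS):
            raise ValueError("code table must cover all 20 amino acids")
        if self.codon_to_symbol["ATG"] != "M":
            raise ValueError("ATG must encode methionine")

    @classmethod
    def from_file(cls, path) -> "GeneticCodeTable":
        codon_to_symbol: dict[str, str] = {}
        three: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                codon_to_symbol[row["codon"]] = row["symbol"]
                three[row["symbol"]] = row["name"]
        return cls(codon_to_symbol, three)


def _packaged_table() -> GeneticCodeTable:
    ref = resources.files("snpsat") / "data" / "genetic_code.tsv"
    with resources.as_file(ref) as path:
        return GeneticCodeTable.from_file(path)


STANDARD_TABLE = _packaged_table()

_GROUP_MEMBERS: dict[ResidueGroup, frozenset[str]] = {
    ResidueGroup.POSITIVE: frozenset("RHK"),
    ResidueGroup.NEGATIVE: frozenset("DE"),
    ResidueGroup.POLAR: frozenset("STNQ"),
    ResidueGroup.SPECIAL: frozenset("CGP"),
    ResidueGroup.HYDROPHOBIC: frozenset("AVILMFYW"),
    ResidueGroup.STOP: frozenset(STOP),
}

_GROUP_OF: dict[str, ResidueGroup] = {
    sym: grp for grp, members in _GROUP_MEMBERS.items() for sym in members
}


def normalize_codon(codon: str) -> str:
    """Uppercase, map U->T and validate a 3-letter codon.

    Raises :class:`InvalidAlphabetError` naming the 1-based offending
    position, or ``ValueError`` if the length is not 3.  Ambiguity codes
    (N, R, Y, ...) are rejected: the saturation enumeration is defined
    over unambiguous bases only.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    out = codon.upper().replace("U", "T")
    for i, ch in enumerate(out, start=1):
        if ch not in _BASES:
            raise InvalidAlphabetError(ch, i)
    return out


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard code; stops yield ``"*"``."""
    return STANDARD_TABLE.codon_to_symbol[normalize_codon(codon)]


def group_of(symbol: str) -> ResidueGroup:
    """Physicochemical group of a residue symbol (or STOP sentinel)."""
    try:
        return _GROUP_OF[symbol]
    except KeyError:
        raise InvalidSymbolError(symbol) from None


def group_members(group: ResidueGroup) -> frozenset[str]:
    return _GROUP_MEMBERS[group]


def three_letter(symbol: str) -> str:
    """Three-letter name for a one-letter symbol (``Stp`` for the stop)."""
    try:
        return STANDARD_TABLE.three_letter[symbol]
    except KeyError:
        raise InvalidSymbolError(symbol) from None


def codon_count_by_symbol() -> dict[str, int]:
    """How many of the 64 codons encode each symbol (stop included)."""
    return dict(Counter(STANDARD_TABLE.codon_to_symbol.values()))


def codon_count_by_group() -> dict[ResidueGroup, int]:
    """How many of the 64 codons fall in each physicochemical group."""
    counts: Counter[ResidueGroup] = Counter(
        group_of(sym) for sym in STANDARD_TABLE.codon_to_symbol.values()
    )
    return dict(counts)
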