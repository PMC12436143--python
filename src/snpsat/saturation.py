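"""The saturation engine: CDS validation, translation, exhaustive SNP
enumeration and consequence classification.

A coding sequence of length L yields exactly 3L single-nucleotide
variants (3 alternative bases at each position), each mutated one base
at a time against the original sequence.  Every variant falls in
exactly one of six consequence classes:

===================  ====================================================
SYNONYMOUS           same amino acid (silent)
SAME_GROUP_MISSENSE  different amino acid, same physicochemical group
CROSS_GROUP_MISSENSE different amino acid, different group
NONSENSE             sense codon -> stop codon (truncation)
STOP_RETAINED        stop codon -> a different stop codon
STOP_LOSS            stop codon -> sense codon (read-through)
===================  ====================================================

Coordinates are 1-based throughout: nucleotide positions 1..L, codon
indices 1..L/3, protein positions counting the initiator Met as 1.
The engine is single-strand, sense-strand only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Optional

from .genetic_code import (
    STOP,
    AMINO_ACIDS,
    InvalidAlphabetError,
    InvalidSymbolError,
    ResidueGroup,
    group_of,
    translate_codon,
)
from .sneath import SneathMatrix, STOP_SCORE, substitution_score

BASES = "ACGT"


class CdsValidationError(ValueError):
    """Base class for coding-sequence validation failures."""


class CdsLengthError(CdsValidationError):
    pass


class MissingStartCodonError(CdsValidationError):
    pass


class MissingStopCodonError(CdsValidationError):
    pass


class InternalStopError(CdsValidationError):
    pass


@dataclass(frozen=True)
class CodingSequence:
    """A validated CDS: ATG ... terminal stop, no internal stops.

    Construct via :func:`validate_cds`; the constructor assumes an
    already-normalized A/C/G/T string.
    """

    bases: str

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def codon_count(self) -> int:
        return len(self.bases) // 3

    def codon(self, index: int) -> str:
        """The codon at 1-based index."""
        if not 1 <= index <= self.codon_count:
            raise IndexError(f"codon index {index} outside 1..{self.codon_count}")
        return self.bases[3 * (index - 1): 3 * index]

    def codons(self) -> Iterator[str]:
        for i in range(0, len(self.bases), 3):
            yield self.bases[i: i + 3]


def validate_cds(raw: str) -> CodingSequence:
    """Normalize and validate a coding sequence.

    Whitespace is stripped, case folded, U mapped to T.  The sequence
    must have length divisible by 3, start with ATG, end with a stop
    codon and contain no internal stop codon; each failure raises a
    distinct position-reporting error.
    """
    seq = "".join(raw.split()).upper().replace("U", "T")
    for i, ch in enumerate(seq, start=1):
        if ch not in BASES:
            raise InvalidAlphabetError(ch, i)
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise CdsLengthError(
            f"sequence length {len(seq)} is not a positive multiple of 3"
        )
    if seq[:3] != "ATG":
        raise MissingStartCodonError(
            f"sequence must start with ATG, found {seq[:3]!r} at position 1"
        )
    n_codons = len(seq) // 3
    for idx in range(1, n_codons + 1):
        codon = seq[3 * (idx - 1): 3 * idx]
        is_stop = translate_codon(codon) == STOP
        if idx < n_codons and is_stop:
            raise InternalStopError(
                f"internal stop codon {codon} at codon {idx} "
                f"(nucleotide {3 * (idx - 1) + 1})"
            )
        if idx == n_codons and not is_stop:
            raise MissingStopCodonError(
                f"last codon {codon} is not a stop codon"
            )
    return CodingSequence(seq)


def translate(cds: CodingSequence) -> str:
    """Protein sequence of the CDS, excluding the terminal stop."""
    return "".join(translate_codon(c) for c in cds.codons())[:-1]


def residue_composition(
    protein: str, *, include_stop: bool = False
) -> tuple[dict[str, int], dict[ResidueGroup, int]]:
    """Per-symbol and per-group residue counts of a protein.

    With ``include_stop`` one terminal stop is counted on top of the
    residues, so totals equal the codon count of the source CDS.
    """
    symbols = list(protein)
    for sym in symbols:
        if sym not in AMINO_ACIDS and sym != STOP:
            raise InvalidSymbolError(sym)
    if include_stop:
        symbols.append(STOP)
    by_symbol = dict(Counter(symbols))
    by_group = dict(Counter(group_of(s) for s in symbols))
    return by_symbol, by_group


class ConsequenceClass(str, Enum):
    SYNONYMOUS = "SYNONYMOUS"
    SAME_GROUP_MISSENSE = "SAME_GROUP_MISSENSE"
    CROSS_GROUP_MISSENSE = "CROSS_GROUP_MISSENSE"
    NONSENSE = "NONSENSE"
    STOP_RETAINED = "STOP_RETAINED"
    STOP_LOSS = "STOP_LOSS"

    def __str__(self) -> str:
        return self.value


def classify_consequence(original_symbol: str, variant_symbol: str) -> ConsequenceClass:
    """Six-way consequence of an (original, variant) symbol pair.

    The classes are mutually exclusive and exhaustive over all pairs a
    single-nucleotide change can produce.  Same-group vs cross-group
    uses the strict five-way partition (positive and negative charged
    residues are distinct groups here; aggregate views may merge them).
    """
    for sym in (original_symbol, variant_symbol):
        if sym != STOP and sym not in AMINO_ACIDS:
            raise InvalidSymbolError(sym)
    if original_symbol == STOP:
        return (
            ConsequenceClass.STOP_RETAINED
            if variant_symbol == STOP
            else ConsequenceClass.STOP_LOSS
        )
    if variant_symbol == STOP:
        return ConsequenceClass.NONSENSE
    if original_symbol == variant_symbol:
        return ConsequenceClass.SYNONYMOUS
    if group_of(original_symbol) == group_of(variant_symbol):
        return ConsequenceClass.SAME_GROUP_MISSENSE
    return ConsequenceClass.CROSS_GROUP_MISSENSE


@dataclass(frozen=True)
class SnpRecord:
    """One single-nucleotide variant of one codon, fully annotated."""

    nt_position: int          # 1-based position in the CDS
    codon_index: int          # 1-based codon number
    offset_in_codon: int      # 1..3
    ref_base: str
    alt_base: str
    original_codon: str
    variant_codon: str
    original_symbol: str
    variant_symbol: str
    original_group: ResidueGroup
    variant_group: ResidueGroup
    consequence: ConsequenceClass
    sneath_score: int


def enumerate_snps(
    cds: CodingSequence,
    matrix: SneathMatrix,
    *,
    stop_loss_score: int = STOP_SCORE,
) -> list[SnpRecord]:
    """All 3L single-nucleotide variants of a CDS, annotated and scored.

    Each base is mutated against the original sequence (no compound
    variants).  Records are ordered by nucleotide position, then
    alphabetically by alternative base, so outputs are byte-stable.
    """
    records: list[SnpRecord] = []
    for codon_index in range(1, cds.codon_count + 1):
        codon = cds.codon(codon_index)
        original_symbol = translate_codon(codon)
        original_group = group_of(original_symbol)
        for offset in range(1, 4):
            ref = codon[offset - 1]
            for alt in BASES:
                if alt == ref:
                    continue
                variant_codon = codon[: offset - 1] + alt + codon[offset:]
                variant_symbol = translate_codon(variant_codon)
                records.append(
                    SnpRecord(
                        nt_position=3 * (codon_index - 1) + offset,
                        codon_index=codon_index,
                        offset_in_codon=offset,
                        ref_base=ref,
                        alt_base=alt,
                        original_codon=codon,
                        variant_codon=variant_codon,
                        original_symbol=original_symbol,
                        variant_symbol=variant_symbol,
                        original_group=original_group,
                        variant_group=group_of(variant_symbol),
                        consequence=classify_consequence(
                            original_symbol, variant_symbol
                        ),
                        sneath_score=substitution_score(
                            original_symbol,
                            variant_symbol,
                            matrix,
                            stop_loss_score=stop_loss_score,
                        ),
                    )
                )
    return records


def find_residue_positions(protein: str, symbol: str) -> list[int]:
    """Sorted 1-based positions of a residue symbol in a protein."""
    if symbol != STOP and symbol not in AMINO_ACIDS:
        raise InvalidSymbolError(symbol)
    return [i for i, sym in enumerate(protein, start=1) if sym == symbol]
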