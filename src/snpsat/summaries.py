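"""Aggregate views over a saturation enumeration.

Builds the headline consequence partition, per-residue substitution
tables, amino-acid frequency shifts between the original protein and
the variant pool, and mean Sneath scores per original residue.

Headline partition conventions
------------------------------
The four-way headline partition (no change / same group / stop gained /
different group) condenses the six fine-grained consequence classes.
Two conventions are configurable because aggregate reports in this
field differ on them:

* ``merge_charged`` (default True): positively and negatively charged
  residues are treated as a single "charged" category when deciding
  whether a missense substitution stays within its group.  Chemically
  this counts conservative charged-site swaps (e.g. Glu->Lys at a
  surface salt bridge position, Asp->His) as "similar"; it is also the
  convention under which the B2M worked example partitions 1080
  variants into 239 / 274 / 57 / 510.
* ``stop_fold`` (default TERMINAL_TO_DIFFERENT_GROUP): where the
  terminal stop codon's nine variants land.  By default all of them
  (stop-retained and stop-loss alike) are folded into the
  "different group" bucket — again the convention the B2M headline
  partition follows.  Alternatives fold stop-retained variants with the
  silent ("no change") bucket or with the stop-gain bucket.

Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genetic_code import (
    CHARGED_GROUPS,
    STOP,
    AMINO_ACIDS,
    InvalidSymbolError,
    ResidueGroup,
    group_of,
)
from .saturation import (
    CodingSequence,
    ConsequenceClass,
    SnpRecord,
    residue_composition,
    translate,
)

#: Fixed column order of the per-SNP table (I/O and summaries agree on it).
RECORD_COLUMNS = [
    "nt_position",
    "codon_index",
    "offset_in_codon",
    "ref_base",
    "alt_base",
    "original_codon",
    "variant_codon",
    "original_aa",
    "variant_aa",
    "original_group",
    "variant_group",
    "consequence",
    "sneath_score",
]

PARTITION_LABELS = ["no_change", "same_group", "stop_gain", "different_group"]


class StopFold(str, Enum):
    """Where the terminal stop codon's variants land in the headline partition."""

    TERMINAL_TO_DIFFERENT_GROUP = "terminal_to_different_group"
    RETAINED_WITH_NO_CHANGE = "retained_with_no_change"
    RETAINED_WITH_STOP_GAIN = "retained_with_stop_gain"


DEFAULT_STOP_FOLD = StopFold.TERMINAL_TO_DIFFERENT_GROUP


def round_percentage(count: int, total: int) -> float:
    """100*count/total, rounded half-up to one decimal."""
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _headline_bucket(
    record: SnpRecord, stop_fold: StopFold, merge_charged: bool
) -> str:
    cons = record.consequence
    if cons is ConsequenceClass.SYNONYMOUS:
        return "no_change"
    if cons is ConsequenceClass.NONSENSE:
        return "stop_gain"
    if cons is ConsequenceClass.STOP_RETAINED:
        return {
            StopFold.TERMINAL_TO_DIFFERENT_GROUP: "different_group",
            StopFold.RETAINED_WITH_NO_CHANGE: "no_change",
            StopFold.RETAINED_WITH_STOP_GAIN: "stop_gain",
        }[stop_fold]
    if cons is ConsequenceClass.STOP_LOSS:
        return "different_group"
    # missense
    if cons is ConsequenceClass.SAME_GROUP_MISSENSE:
        return "same_group"
    if (
        merge_charged
        and record.original_group in CHARGED_GROUPS
        and record.variant_group in CHARGED_GROUPS
    ):
        return "same_group"
    return "different_group"


def consequence_partition(
    records: Sequence[SnpRecord],
    *,
    stop_fold: StopFold = DEFAULT_STOP_FOLD,
    merge_charged: bool = True,
) -> dict[str, tuple[int, float]]:
    """Four-way headline partition: label -> (count, percentage).

    Counts sum to ``len(records)``; percentages are rounded half-up to
    one decimal and sum to ~100.
    """
    if not records:
        raise ValueError("cannot partition an empty record list")
    counts = Counter(
        _headline_bucket(r, stop_fold, merge_charged) for r in records
    )
    total = len(records)
    return {
        label: (counts.get(label, 0), round_percentage(counts.get(label, 0), total))
        for label in PARTITION_LABELS
    }


def folded_effect_percentages(
    partition: Mapping[str, tuple[int, float]]
) -> tuple[float, float]:
    """(no-or-minimal, major) effect percentages.

    Sums the silent + same-group buckets against the stop-gain +
    different-group buckets (47.5 vs 52.5 for the B2M example).
    """
    minimal = partition["no_change"][1] + partition["same_group"][1]
    major = partition["stop_gain"][1] + partition["different_group"][1]
    return minimal, major


def _check_symbol(symbol: str) -> None:
    if symbol != STOP and symbol not in AMINO_ACIDS:
        raise InvalidSymbolError(symbol)


def per_residue_substitution_table(
    records: Iterable[SnpRecord], symbol: str
) -> dict[str, int]:
    """Variant-symbol counts over all SNPs whose original symbol matches.

    The counts sum to 9 x (number of codons of ``symbol`` in the CDS);
    synonymous events appear under the original symbol itself.  Empty if
    the symbol does not occur.
    """
    _check_symbol(symbol)
    counts = Counter(
        r.variant_symbol for r in records if r.original_symbol == symbol
    )
    return dict(counts)


def group_substitution_table(
    records: Iterable[SnpRecord], symbol: str
) -> dict[ResidueGroup, int]:
    """Variant-group counts for a given original symbol."""
    _check_symbol(symbol)
    counts = Counter(
        r.variant_group for r in records if r.original_symbol == symbol
    )
    return dict(counts)


def frequency_shift(
    cds: CodingSequence, records: Sequence[SnpRecord]
) -> pd.DataFrame:
    """Per-symbol occurrence frequencies, original protein vs variant pool.

    Original percentages are over the codon count (stop included, 120
    for B2M); variant percentages are over the number of SNPs (1080 for
    B2M).  Both percentage columns sum to 100.
    """
    if len(records) != 3 * cds.length:
        raise ValueError(
            f"records ({len(records)}) do not match the CDS "
            f"(expected {3 * cds.length})"
        )
    for r in records:
        if r.original_codon != cds.codon(r.codon_index):
            raise ValueError(
                f"record at codon {r.codon_index} does not derive from this CDS"
            )
    by_symbol, _ = residue_composition(translate(cds), include_stop=True)
    variant_counts = Counter(r.variant_symbol for r in records)
    symbols = sorted(AMINO_ACIDS) + [STOP]
    total_orig = cds.codon_count
    total_var = len(records)
    frame = pd.DataFrame(
        {
            "original_count": [by_symbol.get(s, 0) for s in symbols],
            "original_pct": [
                100 * by_symbol.get(s, 0) / total_orig for s in symbols
            ],
            "variant_count": [variant_counts.get(s, 0) for s in symbols],
            "variant_pct": [
                100 * variant_counts.get(s, 0) / total_var for s in symbols
            ],
        },
        index=pd.Index(symbols, name="symbol"),
    )
    return frame


def mean_sneath_by_original(records: Iterable[SnpRecord]) -> dict[str, float]:
    """Arithmetic mean Sneath score per original symbol (STOP included).

    The mean is over all SNPs sharing the original symbol, i.e. over
    9 x (codon occurrences) records; scores embed the extended 0/100
    conventions chosen at enumeration time.
    """
    sums: Counter[str] = Counter()
    counts: Counter[str] = Counter()
    for r in records:
        sums[r.original_symbol] += r.sneath_score
        counts[r.original_symbol] += 1
    if not counts:
        raise ValueError("cannot summarize an empty record list")
    return {sym: sums[sym] / counts[sym] for sym in sorted(counts)}


def records_to_frame(records: Sequence[SnpRecord]) -> pd.DataFrame:
    """Per-SNP table with the fixed column order :data:`RECORD_COLUMNS`."""
    frame = pd.DataFrame(
        {
            "nt_position": [r.nt_position for r in records],
            "codon_index": [r.codon_index for r in records],
            "offset_in_codon": [r.offset_in_codon for r in records],
            "ref_base": [r.ref_base for r in records],
            "alt_base": [r.alt_base for r in records],
            "original_codon": [r.original_codon for r in records],
            "variant_codon": [r.variant_codon for r in records],
            "original_aa": [r.original_symbol for r in records],
            "variant_aa": [r.variant_symbol for r in records],
            "original_group": [str(r.original_group) for r in records],
            "variant_group": [str(r.variant_group) for r in records],
            "consequence": [str(r.consequence) for r in records],
            "sneath_score": [r.sneath_score for r in records],
        }
    )
    return frame[RECORD_COLUMNS]


def frame_to_records(frame: pd.DataFrame) -> list[SnpRecord]:
    """Inverse of :func:`records_to_frame` (round-trip safe)."""
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            SnpRecord(
                nt_position=int(row.nt_position),
                codon_index=int(row.codon_index),
                offset_in_codon=int(row.offset_in_codon),
                ref_base=row.ref_base,
                alt_base=row.alt_base,
                original_codon=row.original_codon,
                variant_codon=row.variant_codon,
                original_symbol=row.original_aa,
                variant_symbol=row.variant_aa,
                original_group=ResidueGroup(row.original_group),
                variant_group=ResidueGroup(row.variant_group),
                consequence=ConsequenceClass(row.consequence),
                sneath_score=int(row.sneath_score),
            )
        )
    return records


@dataclass(frozen=True)
class SaturationSummary:
    """Bundle of the aggregate views over one enumeration."""

    total_snps: int
    partition: dict[str, tuple[int, float]]
    variant_aa_counts: dict[str, int]
    variant_group_counts: dict[ResidueGroup, int]
    original_vs_variant_freq: pd.DataFrame
    mean_sneath: dict[str, float]

    @classmethod
    def from_records(
        cls,
        cds: CodingSequence,
        records: Sequence[SnpRecord],
        *,
        stop_fold: StopFold = DEFAULT_STOP_FOLD,
        merge_charged: bool = True,
    ) -> "SaturationSummary":
        return cls(
            total_snps=len(records),
            partition=consequence_partition(
                records, stop_fold=stop_fold, merge_charged=merge_charged
            ),
            variant_aa_counts=dict(Counter(r.variant_symbol for r in records)),
            variant_group_counts=dict(Counter(r.variant_group for r in records)),
            original_vs_variant_freq=frequency_shift(cds, records),
            mean_sneath=mean_sneath_by_original(records),
        )
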