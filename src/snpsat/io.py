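"""Sequence reading, table writing, run configuration and the pipeline.

The tool processes one coding sequence per invocation (batch mode is a
shell loop): read the sequence, enumerate its single-nucleotide
variants, and write a per-SNP table plus summary tables with fixed
column orders so outputs are byte-reproducible.
"""

from __future__ import annotations

import io as _io
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

from . import sneath
from .genetic_code import STOP, translate_codon
from .saturation import CodingSequence, enumerate_snps, translate, validate_cds
from .summaries import (
    DEFAULT_STOP_FOLD,
    RECORD_COLUMNS,
    SaturationSummary,
    SnpRecord,
    StopFold,
    frame_to_records,
    records_to_frame,
)

logger = logging.getLogger("snpsat")

#: the 61 sense codons, in lexicographic order (seed-stable sampling)
SENSE_CODONS = sorted(
    b1 + b2 + b3
    for b1 in "ACGT"
    for b2 in "ACGT"
    for b3 in "ACGT"
    if translate_codon(b1 + b2 + b3) != STOP
)
STOP_CODONS = ["TAA", "TAG", "TGA"]


class MultiRecordFastaError(ValueError):
    """The engine is single-CDS; multi-record FASTA input is rejected."""


def read_sequence(source: str | Path) -> str:
    """Read a raw nucleotide string from a file path or pass a literal.

    Files may be single-record FASTA (header logged, then ignored) or
    plain text; whitespace is stripped.  A literal sequence string is
    returned as-is (whitespace stripped).  Multi-record FASTA raises
    :class:`MultiRecordFastaError`.
    """
    path = Path(source)
    if not path.exists():
        # treat as a literal sequence
        return "".join(str(source).split())
    text = path.read_text()
    if text.lstrip().startswith(">"):
        records = list(SeqIO.parse(_io.StringIO(text), "fasta"))
        if len(records) != 1:
            raise MultiRecordFastaError(
                f"{path} holds {len(records)} FASTA records; exactly 1 expected"
            )
        logger.info("read FASTA record %r from %s", records[0].id, path)
        return str(records[0].seq)
    return "".join(text.split())


def generate_random_cds(n_codons: int, seed: int) -> CodingSequence:
    """A random valid CDS: ATG + (n_codons-2) sense codons + a stop.

    Internal codons are drawn uniformly from the 61 sense codons, so no
    internal stop can arise by construction and generation is linear
    and seed-stable.  Property-test fixture; requires ``n_codons >= 2``.
    """
    if n_codons < 2:
        raise ValueError(f"a CDS needs at least 2 codons, got {n_codons}")
    rng = random.Random(seed)
    internal = rng.choices(SENSE_CODONS, k=n_codons - 2)
    stop = rng.choice(STOP_CODONS)
    return validate_cds("ATG" + "".join(internal) + stop)


_ALLOWED_STOP_LOSS = {0, 100} | set(range(5, 44))


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_path`` / ``sequence`` must be given.
    ``stop_loss_score`` must lie in {0} ∪ [5,43] ∪ {100} — the score
    vocabulary of the extended Sneath convention.
    """

    input_path: Optional[Path] = None
    sequence: Optional[str] = None
    matrix_path: Optional[Path] = None
    stop_fold: StopFold = DEFAULT_STOP_FOLD
    merge_charged: bool = True
    stop_loss_score: int = sneath.STOP_SCORE
    out_dir: Path = field(default_factory=lambda: Path("."))
    fmt: str = "tsv"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sequence is None):
            raise ValueError(
                "exactly one of input_path / sequence must be supplied"
            )
        if self.stop_loss_score not in _ALLOWED_STOP_LOSS:
            raise ValueError(
                f"stop_loss_score {self.stop_loss_score} outside "
                "{0} u [5,43] u {100}"
            )
        if self.fmt not in ("tsv", "csv"):
            raise ValueError(f"format must be tsv or csv, got {self.fmt!r}")


def _sep(fmt: str) -> str:
    return "\t" if fmt == "tsv" else ","


def write_records(
    records: list[SnpRecord], path: Path | str, fmt: str = "tsv"
) -> Path:
    """Write the per-SNP table (fixed column order) as TSV or CSV."""
    path = Path(path)
    records_to_frame(records).to_csv(path, sep=_sep(fmt), index=False)
    return path


def read_records(path: Path | str) -> list[SnpRecord]:
    """Read a per-SNP table back into records (round-trip inverse)."""
    path = Path(path)
    sep = "\t" if path.suffix != ".csv" else ","
    frame = pd.read_csv(path, sep=sep, dtype={c: str for c in RECORD_COLUMNS})
    missing = [c for c in RECORD_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path} is missing columns {missing}")
    return frame_to_records(frame)


def run_pipeline(config: RunConfig) -> tuple[list[SnpRecord], SaturationSummary]:
    """Validate, enumerate, summarize, and write all output tables.

    Writes ``snp_table.<fmt>``, ``partition.<fmt>``,
    ``variant_counts.<fmt>``, ``frequency_shift.<fmt>`` and
    ``mean_sneath.<fmt>`` into ``config.out_dir``.  Validation errors
    propagate before anything is written (no partial outputs).
    """
    raw = (
        config.sequence
        if config.sequence is not None
        else read_sequence(config.input_path)
    )
    cds = validate_cds(raw)
    matrix = sneath.load_matrix(config.matrix_path)
    records = enumerate_snps(
        cds, matrix, stop_loss_score=config.stop_loss_score
    )
    summary = SaturationSummary.from_records(
        cds,
        records,
        stop_fold=config.stop_fold,
        merge_charged=config.merge_charged,
    )
    logger.info(
        "CDS length %d nt, %d codons, %d SNPs; partition %s",
        cds.length,
        cds.codon_count,
        summary.total_snps,
        {k: v[0] for k, v in summary.partition.items()},
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sep = _sep(config.fmt)
    ext = config.fmt

    write_records(records, out / f"snp_table.{ext}", config.fmt)

    part = pd.DataFrame(
        [
            {"bucket": label, "count": c, "percent": p}
            for label, (c, p) in summary.partition.items()
        ]
    )
    part.to_csv(out / f"partition.{ext}", sep=sep, index=False)

    counts = pd.DataFrame(
        sorted(summary.variant_aa_counts.items()),
        columns=["variant_aa", "count"],
    )
    counts.to_csv(out / f"variant_counts.{ext}", sep=sep, index=False)

    summary.original_vs_variant_freq.to_csv(
        out / f"frequency_shift.{ext}", sep=sep
    )

    means = pd.DataFrame(
        sorted(summary.mean_sneath.items()),
        columns=["original_aa", "mean_sneath"],
    )
    means.to_csv(out / f"mean_sneath.{ext}", sep=sep, index=False)

    return records, summary
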