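"""Packaged reference data: the B2M worked example and data-file paths.

Beta-2-microglobulin (B2M) is the smallest immunoglobulin-domain
protein: a single 119-residue domain whose fold is pinned by one
disulfide bond (Cys45-Cys100).  Its mature coding sequence — 360
nucleotides from the ATG start codon through the TAA stop — is the
standing worked example for the saturation analysis and ships with the
package, together with its translation.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

from Bio import SeqIO

from .saturation import CodingSequence, validate_cds

_FIXTURE_FILES = [
    "b2m_cds.fasta",
    "b2m_protein.fasta",
    "genetic_code.tsv",
    "sneath_synthetic.tsv",
]


def _data_path(name: str) -> Path:
    ref = resources.files("snpsat") / "data" / name
    with resources.as_file(ref) as path:
        return Path(path)


def _read_single_fasta(name: str) -> str:
    records = list(SeqIO.parse(_data_path(name), "fasta"))
    assert len(records) == 1
    return str(records[0].seq)


def b2m_cds() -> CodingSequence:
    """The validated 360-nt mature B2M coding sequence (120 codons)."""
    return validate_cds(_read_single_fasta("b2m_cds.fasta"))


def b2m_protein() -> str:
    """The 119-residue mature B2M protein sequence."""
    return _read_single_fasta("b2m_protein.fasta")


def default_matrix_path() -> Path:
    """Path of the packaged (synthetic stand-in) Sneath matrix file."""
    return _data_path("sneath_synthetic.tsv")


def genetic_code_path() -> Path:
    """Path of the packaged genetic-code table."""
    return _data_path("genetic_code.tsv")


def list_fixtures() -> list[str]:
    return list(_FIXTURE_FILES)


def write_fixtures(out_dir: Path | str) -> list[Path]:
    """Copy every packaged data file into a directory; returns the copies."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name in _FIXTURE_FILES:
        dest = out / name
        shutil.copyfile(_data_path(name), dest)
        written.append(dest)
    return written
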