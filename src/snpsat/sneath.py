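"""Sneath chemical-dissimilarity scoring of amino-acid substitutions.

The Sneath index is a dissimilarity score between amino-acid pairs
derived from a large set of physicochemical properties; published
values span 5 (Leu-Ile, the most alike pair) to 43 (Pro-Glu and
Pro-Arg, the most dissimilar).  For variant scoring the index is
extended by two conventions: 0 when the substitution leaves the residue
unchanged (synonymous), and 100 when a stop codon is involved (a
truncation dwarfs any chemical change).

The packaged matrix (``data/sneath_synthetic.tsv``) is a synthetic
stand-in: only five published cells are pinned exactly (Leu-Ile 5,
Pro-Glu 43, Pro-Arg 43, Asp-Asn 14, Ala-Pro 16); the rest are
synthesised from standard physicochemical descriptors and mapped onto
the 5-43 range (see ``scripts/build_data_files.py``).  A user-supplied
matrix can replace it via :func:`load_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

from .genetic_code import AMINO_ACIDS, STOP, InvalidSymbolError

NO_CHANGE_SCORE = 0
STOP_SCORE = 100
MIN_SCORE = 5
MAX_SCORE = 43

#: The values the source text prints; asserted at load time so a
#: mistranscribed or corrupted matrix file fails fast.
ANCHOR_SCORES: dict[frozenset, int] = {
    frozenset("LI"): 5,
    frozenset("PE"): 43,
    frozenset("PR"): 43,
    frozenset("DN"): 14,
    frozenset("AP"): 16,
}


class SneathMatrixError(ValueError):
    """The matrix file violates a structural invariant."""


@dataclass(frozen=True)
class SneathMatrix:
    """Symmetric 20x20 amino-acid dissimilarity table, diagonal 0."""

    _scores: Mapping[tuple[str, str], int]

    def score(self, a: str, b: str) -> int:
        """Dissimilarity between two amino acids; 0 if identical."""
        for sym in (a, b):
            if sym not in AMINO_ACIDS:
                raise InvalidSymbolError(sym)
        if a == b:
            return 0
        return self._scores[(a, b)]

    @classmethod
    def from_pairs(cls, pairs: Mapping[frozenset, int]) -> "SneathMatrix":
        expected = {
            frozenset((a, b))
            for a in AMINO_ACIDS
            for b in AMINO_ACIDS
            if a < b
        }
        missing = expected - set(pairs)
        if missing:
            some = "/".join(sorted(next(iter(missing))))
            raise SneathMatrixError(
                f"matrix is missing {len(missing)} amino-acid pairs (e.g. {some})"
            )
        for key, value in pairs.items():
            if not MIN_SCORE <= value <= MAX_SCORE:
                a, b = sorted(key)
                raise SneathMatrixError(
                    f"score({a},{b}) = {value} outside the {MIN_SCORE}-{MAX_SCORE} range"
                )
        flat = {}
        for key, value in pairs.items():
            a, b = sorted(key)
            flat[(a, b)] = flat[(b, a)] = int(value)
        return cls(flat)


def load_matrix(
    path: Optional[Path | str] = None, *, check_anchors: bool = True
) -> SneathMatrix:
    """Load a Sneath matrix from a TSV file (packaged stand-in by default).

    The file has a header row of one-letter codes and 20 labelled rows.
    Full square matrices must be symmetric; lower-triangular files are
    accepted and mirrored.  Structural violations (missing amino acid,
    asymmetric cell, out-of-range value) raise :class:`SneathMatrixError`.
    With ``check_anchors`` the five published values are asserted too.
    """
    if path is None:
        ref = resources.files("snpsat") / "data" / "sneath_synthetic.tsv"
        with resources.as_file(ref) as p:
            return load_matrix(p, check_anchors=check_anchors)

    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise SneathMatrixError(f"empty matrix file: {path}")
    header = lines[0].split("\t")
    cols = [c for c in header if c]  # leading corner cell may be empty
    if sorted(cols) != sorted(AMINO_ACIDS):
        raise SneathMatrixError(
            f"header must list the 20 amino acids, got {cols!r}"
        )
    seen: dict[tuple[str, str], int] = {}
    row_labels = []
    for ln in lines[1:]:
        cells = ln.split("\t")
        label = cells[0]
        if label not in AMINO_ACIDS:
            raise SneathMatrixError(f"unknown row label {label!r}")
        row_labels.append(label)
        for col, cell in zip(cols, cells[1:]):
            if cell == "":
                continue  # triangular file
            try:
                value = int(cell)
            except ValueError:
                raise SneathMatrixError(
                    f"non-integer cell ({label},{col}): {cell!r}"
                ) from None
            if label == col:
                if value != 0:
                    raise SneathMatrixError(f"diagonal ({label},{label}) must be 0")
                continue
            key = (min(label, col), max(label, col))
            if key in seen and seen[key] != value:
                raise SneathMatrixError(
                    f"asymmetric cell: score({key[0]},{key[1]}) given as "
                    f"both {seen[key]} and {value}"
                )
            seen[key] = value
    if sorted(row_labels) != sorted(AMINO_ACIDS):
        raise SneathMatrixError("matrix rows must cover the 20 amino acids")
    matrix = SneathMatrix.from_pairs({frozenset(k): v for k, v in seen.items()})
    if check_anchors:
        for pair, expected in ANCHOR_SCORES.items():
            a, b = sorted(pair)
            got = matrix.score(a, b)
            if got != expected:
                raise SneathMatrixError(
                    f"anchor mismatch: score({a},{b}) = {got}, expected {expected}"
                )
    return matrix


def substitution_score(
    original: str,
    variant: str,
    matrix: SneathMatrix,
    *,
    stop_loss_score: int = STOP_SCORE,
) -> int:
    """Extended Sneath score for a single-nucleotide substitution.

    Rules, in order: identical symbols (including stop->stop) score 0;
    any variant stop (nonsense) scores 100; a lost stop (read-through)
    scores ``stop_loss_score`` (default 100 — disrupting termination is
    treated as severely as truncation); otherwise the matrix value.
    """
    for sym in (original, variant):
        if sym != STOP and sym not in AMINO_ACIDS:
            raise InvalidSymbolError(sym)
    if original == variant:
        return NO_CHANGE_SCORE
    if variant == STOP:
        return STOP_SCORE
    if original == STOP:
        return stop_loss_score
    return matrix.score(original, variant)
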