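"""Regenerate the plain-text data files packaged under src/snpsat/data/.

Two files are produced:

* ``genetic_code.tsv`` — the standard genetic code (NCBI translation
  table 1) with the five-way physicochemical group of each residue.
* ``sneath_synthetic.tsv`` — a SYNTHETIC stand-in for the Sneath (1966)
  amino-acid chemical-dissimilarity matrix.  Only five cells of the real
  matrix are public anchors here (Leu-Ile 5; Pro-Glu 43; Pro-Arg 43;
  Asp-Asn 14; Ala-Pro 16); the remaining cells are synthesised from
  standard physicochemical descriptors (Kyte-Doolittle hydropathy,
  Zamyatnin residue volume, net charge, aromaticity, conformational
  flags for Pro/Gly, sulfur content, group membership), affinely mapped
  onto the published 5-43 range, and the anchor cells are then set to
  their printed values.  The stand-in preserves symmetry, integer
  values, the 5-43 range and the anchors, which is what the scoring
  layer validates.

Deterministic; run from the repository root:

    python scripts/build_data_files.py
"""

from __future__ import annotations

import math
from pathlib import Path

from Bio.Data import CodonTable

DATA = Path(__file__).resolve().parent.parent / "src" / "snpsat" / "data"

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Stp",
}

GROUPS = {
    "POSITIVE": "RHK",
    "NEGATIVE": "DE",
    "POLAR": "STNQ",
    "SPECIAL": "CGP",
    "HYDROPHOBIC": "AVILMFYW",
}

# Kyte-Doolittle hydropathy index
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

# Zamyatnin residue volumes, cubic angstroms
VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

CHARGE = {"K": 1.0, "R": 1.0, "H": 0.5, "D": -1.0, "E": -1.0}
AROMATIC = set("FWYH")
SULFUR = set("CM")

ANCHORS = {
    frozenset("LI"): 5,
    frozenset("PE"): 43,
    frozenset("PR"): 43,
    frozenset("DN"): 14,
    frozenset("AP"): 16,
}


def write_genetic_code() -> None:
    table = CodonTable.unambiguous_dna_by_id[1]
    group_of = {a: g for g, aas in GROUPS.items() for a in aas}
    group_of["*"] = "STOP"
    rows = []
    for b1 in "ACGT":
        for b2 in "ACGT":
            for b3 in "ACGT":
                codon = b1 + b2 + b3
                sym = "*" if codon in table.stop_codons else table.forward_table[codon]
                rows.append((codon, sym, THREE_LETTER[sym], group_of[sym]))
    lines = ["codon\tsymbol\tname\tgroup"]
    lines += ["\t".join(r) for r in rows]
    (DATA / "genetic_code.tsv").write_text("\n".join(lines) + "\n")


def _zscore(values: dict[str, float]) -> dict[str, float]:
    mean = sum(values.values()) / len(values)
    sd = math.sqrt(sum((v - mean) ** 2 for v in values.values()) / len(values))
    return {k: (v - mean) / sd for k, v in values.items()}


def write_sneath_stand_in() -> None:
    h = _zscore(HYDROPATHY)
    v = _zscore(VOLUME)
    group_of = {a: g for g, aas in GROUPS.items() for a in aas}

    def raw(a: str, b: str) -> float:
        d2 = (h[a] - h[b]) ** 2 + (v[a] - v[b]) ** 2
        d2 += 1.5 * (CHARGE.get(a, 0.0) - CHARGE.get(b, 0.0)) ** 2
        d2 += 0.8 * (group_of[a] != group_of[b])
        d2 += 0.5 * ((a in AROMATIC) - (b in AROMATIC)) ** 2
        d2 += 1.5 * ((a == "P") - (b == "P")) ** 2
        d2 += 0.8 * ((a == "G") - (b == "G")) ** 2
        d2 += 0.5 * ((a in SULFUR) - (b in SULFUR)) ** 2
        return math.sqrt(d2)

    pairs = [(a, b) for i, a in enumerate(AA_ORDER) for b in AA_ORDER[i + 1:]]
    dists = {frozenset(p): raw(*p) for p in pairs}
    lo, hi = min(dists.values()), max(dists.values())
    scores = {
        k: round(5 + 38 * (d - lo) / (hi - lo)) for k, d in dists.items()
    }
    scores.update(ANCHORS)
    assert all(5 <= s <= 43 for s in scores.values())

    lines = ["\t".join([""] + list(AA_ORDER))]
    for a in AA_ORDER:
        cells = [a]
        for b in AA_ORDER:
            cells.append("0" if a == b else str(scores[frozenset((a, b))]))
        lines.append("\t".join(cells))
    (DATA / "sneath_synthetic.tsv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    DATA.mkdir(parents=True, exist_ok=True)
    write_genetic_code()
    write_sneath_stand_in()
    print("wrote", DATA / "genetic_code.tsv")
    print("wrote", DATA / "sneath_synthetic.tsv")
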