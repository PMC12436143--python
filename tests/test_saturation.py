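"""CDS validation, translation, enumeration, and the brute-force oracle.

The oracle rebuilds each mutated full-length sequence, re-translates it
entirely with Biopython, diffs the two protein strings and classifies
the consequence with its own grouping table — an independent path from
the engine's per-codon bookkeeping.
"""

from collections import Counter

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

import snpsat
from snpsat import saturation as sat
from snpsat.genetic_code import InvalidAlphabetError, ResidueGroup
from snpsat.io import generate_random_cds

# --- independent grouping/classification for the oracle -------------------
ORACLE_GROUPS = {}
for _grp, _aas in [
    ("pos", "RHK"), ("neg", "DE"), ("pol", "STNQ"),
    ("spe", "CGP"), ("hyd", "AVILMFYW"), ("stp", "*"),
]:
    for _a in _aas:
        ORACLE_GROUPS[_a] = _grp


def oracle_enumerate(bases, matrix):
    """Brute force: mutate the full sequence, re-translate, diff proteins."""
    out = []
    full = str(Seq(bases).translate())  # includes terminal '*'
    for pos in range(len(bases)):
        for alt in "ACGT":
            if alt == bases[pos]:
                continue
            mutated = bases[:pos] + alt + bases[pos + 1:]
            new_full = str(Seq(mutated).translate())
            diffs = [i for i, (x, y) in enumerate(zip(full, new_full)) if x != y]
            assert len(diffs) <= 1
            codon_idx = pos // 3  # 0-based; the only codon that can change
            orig, var = full[codon_idx], new_full[codon_idx]
            if orig == "*":
                cons = "STOP_RETAINED" if var == "*" else "STOP_LOSS"
            elif var == "*":
                cons = "NONSENSE"
            elif orig == var:
                cons = "SYNONYMOUS"
            elif ORACLE_GROUPS[orig] == ORACLE_GROUPS[var]:
                cons = "SAME_GROUP_MISSENSE"
            else:
                cons = "CROSS_GROUP_MISSENSE"
            if orig == var:
                score = 0
            elif var == "*" or orig == "*":
                score = 100
            else:
                score = matrix.score(orig, var)
            out.append((pos + 1, alt, orig, var, cons, score))
    return out


# --- validation ------------------------------------------------------------

def test_validate_b2m_fixture(b2m_cds):
    assert b2m_cds.length == 360
    assert b2m_cds.codon_count == 120
    assert b2m_cds.bases.startswith("ATG") and b2m_cds.bases.endswith("TAA")


def test_validate_normalizes_whitespace_case_and_u():
    cds = sat.validate_cds(" aug\nUGC\ttaa ")
    assert cds.bases == "ATGTGCTAA"


def test_validate_minimal_cds():
    assert sat.validate_cds("ATGTAA").codon_count == 2


@pytest.mark.parametrize(
    "raw,err,fragment",
    [
        ("ATGTA", sat.CdsLengthError, "length 5"),
        ("", sat.CdsLengthError, "length 0"),
        ("TTGTGCTAA", sat.MissingStartCodonError, "position 1"),
        ("ATGTGCTGC", sat.MissingStopCodonError, "TGC"),
        ("ATGTAATGCTAA", sat.InternalStopError, "codon 2"),
        ("ATGNNNTAA", InvalidAlphabetError, "position 4"),
    ],
)
def test_validate_distinct_position_reporting_errors(raw, err, fragment):
    with pytest.raises(err, match=fragment):
        sat.validate_cds(raw)


def test_reverse_complement_does_not_validate(b2m_cds):
    """The engine is sense-strand only."""
    rc = str(Seq(b2m_cds.bases).reverse_complement())
    with pytest.raises(sat.CdsValidationError):
        sat.validate_cds(rc)


# --- translation and composition -------------------------------------------

def test_translate_b2m_gives_printed_protein(b2m_cds, b2m_protein):
    assert sat.translate(b2m_cds) == b2m_protein
    assert len(b2m_protein) == 119


@pytest.mark.parametrize("raw,protein", [("ATGTGCTAA", "MC"), ("ATGTAA", "M")])
def test_translate_toy_sequences(raw, protein):
    assert sat.translate(sat.validate_cds(raw)) == protein


def test_residue_composition_b2m(b2m_protein):
    by_symbol, by_group = sat.residue_composition(b2m_protein, include_stop=True)
    assert sum(by_symbol.values()) == 120
    assert sum(by_group.values()) == 120
    assert by_symbol["C"] == 2 and by_symbol["M"] == 2 and by_symbol["W"] == 2
    assert by_symbol["Q"] == 3
    assert by_symbol["E"] == 9  # letter count over the printed protein
    assert by_group[ResidueGroup.STOP] == 1
    # hydrophobic residues dominate the composition
    assert by_group[ResidueGroup.HYDROPHOBIC] == max(by_group.values())
    no_stop, _ = sat.residue_composition(b2m_protein)
    assert sum(no_stop.values()) == 119


def test_find_residue_positions(b2m_protein):
    assert sat.find_residue_positions(b2m_protein, "C") == [45, 100]
    assert sat.find_residue_positions("M", "W") == []
    h_pos = sat.find_residue_positions(b2m_protein, "H")
    assert all(b2m_protein[p - 1] == "H" for p in h_pos)
    assert len(h_pos) == b2m_protein.count("H")


# --- classification ---------------------------------------------------------

@pytest.mark.parametrize(
    "orig,var,expected",
    [
        ("C", "*", sat.ConsequenceClass.NONSENSE),
        ("*", "Q", sat.ConsequenceClass.STOP_LOSS),
        ("*", "*", sat.ConsequenceClass.STOP_RETAINED),
        ("M", "I", sat.ConsequenceClass.SAME_GROUP_MISSENSE),
        ("D", "N", sat.ConsequenceClass.CROSS_GROUP_MISSENSE),
        ("A", "A", sat.ConsequenceClass.SYNONYMOUS),
        ("D", "H", sat.ConsequenceClass.CROSS_GROUP_MISSENSE),
    ],
)
def test_classify_consequence(orig, var, expected):
    assert sat.classify_consequence(orig, var) == expected


def test_classes_exclusive_and_exhaustive():
    symbols = sorted(snpsat.AMINO_ACIDS) + [snpsat.STOP]
    for a in symbols:
        for b in symbols:
            assert isinstance(sat.classify_consequence(a, b), sat.ConsequenceClass)


# --- enumeration -------------------------------------------------------------

def test_enumerate_counts_and_ordering(b2m_records, b2m_cds):
    assert len(b2m_records) == 3 * b2m_cds.length == 1080
    keys = [(r.nt_position, r.alt_base) for r in b2m_records]
    assert keys == sorted(keys)
    for r in b2m_records:
        assert r.ref_base != r.alt_base
        assert r.nt_position == 3 * (r.codon_index - 1) + r.offset_in_codon
        diff = [i for i in range(3) if r.original_codon[i] != r.variant_codon[i]]
        assert diff == [r.offset_in_codon - 1]


def test_enumerate_minimal_cds(matrix):
    records = sat.enumerate_snps(sat.validate_cds("ATGTAA"), matrix)
    assert len(records) == 18


def test_atg_codon_neighborhood(matrix):
    """The 9 variants of an ATG codon translate to {I x3, L x2, V, K, T, R}."""
    records = sat.enumerate_snps(sat.validate_cds("ATGTAA"), matrix)
    first = [r.variant_symbol for r in records if r.codon_index == 1]
    assert Counter(first) == Counter(
        {"I": 3, "L": 2, "V": 1, "K": 1, "T": 1, "R": 1}
    )


def test_each_codon_yields_its_nine_single_edits(b2m_records, b2m_cds):
    """Set-equality against exhaustive single-position single-letter edits."""
    for idx in range(1, b2m_cds.codon_count + 1):
        codon = b2m_cds.codon(idx)
        expected = {
            codon[:p] + b + codon[p + 1:]
            for p in range(3)
            for b in "ACGT"
            if b != codon[p]
        }
        got = [r.variant_codon for r in b2m_records if r.codon_index == idx]
        assert len(got) == 9
        assert set(got) == expected
        assert codon not in got


def test_six_way_classes_partition_all_records(b2m_records):
    counts = Counter(r.consequence for r in b2m_records)
    assert sum(counts.values()) == 1080


def test_score_constraints_per_class(b2m_records):
    for r in b2m_records:
        if r.consequence is sat.ConsequenceClass.SYNONYMOUS:
            assert r.sneath_score == 0
        elif r.consequence is sat.ConsequenceClass.NONSENSE:
            assert r.sneath_score == 100
        elif r.consequence in (
            sat.ConsequenceClass.SAME_GROUP_MISSENSE,
            sat.ConsequenceClass.CROSS_GROUP_MISSENSE,
        ):
            assert 5 <= r.sneath_score <= 43


def test_enumeration_matches_oracle_on_b2m(b2m_records, b2m_cds, matrix):
    expected = oracle_enumerate(b2m_cds.bases, matrix)
    assert len(expected) == len(b2m_records)
    for rec, (pos, alt, orig, var, cons, score) in zip(b2m_records, expected):
        assert (rec.nt_position, rec.alt_base) == (pos, alt)
        assert rec.original_symbol == orig
        assert rec.variant_symbol == var
        assert rec.consequence.value == cons
        assert rec.sneath_score == score


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    n_codons=st.integers(min_value=2, max_value=30),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_enumeration_matches_oracle_on_random_cds(n_codons, seed, matrix):
    """Record-level equivalence with full-sequence re-translation."""
    cds = generate_random_cds(n_codons, seed)
    records = sat.enumerate_snps(cds, matrix)
    assert len(records) == 3 * cds.length
    expected = oracle_enumerate(cds.bases, matrix)
    got = [
        (r.nt_position, r.alt_base, r.original_symbol, r.variant_symbol,
         r.consequence.value, r.sneath_score)
        for r in records
    ]
    assert got == expected
    counts = Counter(r.consequence for r in records)
    assert sum(counts.values()) == 3 * cds.length
    for r in records:
        assert r.sneath_score == 0 or 5 <= r.sneath_score <= 43 or r.sneath_score == 100
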