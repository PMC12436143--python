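# Methods

## Procedure

Given a validated coding sequence (ATG start, length divisible by 3,
terminal stop, no internal stop; whitespace/case/U-vs-T normalized, and
each violation reported with its position), the engine enumerates every
single-nucleotide substitution: 3 alternative bases at each of the L
positions, each applied alone against the original sequence, giving
exactly 3L variants. Compound variants, indels, splice effects and
genomic coordinates are out of scope; the engine is sense-strand only
(a reverse-complement input simply fails validation). Coordinates are
1-based throughout: nucleotides 1..L, codons 1..L/3, protein positions
counting the initiator Met as 1.

Each variant codon is translated under the standard genetic code (NCBI
table 1 only; ambiguity codes rejected rather than expanded) and the
(original, variant) symbol pair is classified into one of six mutually
exclusive classes: synonymous, same-group missense, cross-group
missense, nonsense, stop-retained, stop-loss. Variants of the terminal
stop codon are classified against the STOP sentinel as the original
symbol; the downstream read-through sequence is not modelled.

Records are ordered by nucleotide position and then alphabetically by
alternative base, so output tables are byte-stable.

## Residue grouping

The five-way grouping — positive {R,H,K}, negative {D,E}, polar
{S,T,N,Q}, special {C,G,P}, hydrophobic {A,V,I,L,M,F,Y,W} — is the
unique partition consistent with the per-group codon counts
10/4/14/10/23 under the standard code. The stop codons form a sixth
pseudo-group of 3 codons.

## Headline partition conventions

The four-way headline partition (no change / same group / stop gained /
different group) condenses the six classes and carries two switchable
conventions, whose defaults were fixed by enumerating the B2M example
and checking which combination yields a self-consistent partition of
the 1080 variants into the reference tallies 239/274/57/510:

- **`merge_charged` (default on).** The same-group tally treats the
  positively and negatively charged residues as one "charged" category,
  so conservative charged-site swaps (Asp↔His, Glu↔Lys; 28 of the B2M
  variants) count as "similar". With `merge_charged` off the strict
  five-way partition is used and the B2M split becomes 246/538.
- **`stop_fold` (default `terminal_to_different_group`).** All nine
  variants of the terminal stop codon (2 stop-retained + 7 stop-loss in
  B2M) are folded into the "different group" bucket: the silent bucket
  then contains exactly the sense-codon synonymous variants, and the
  stop-gain bucket exactly the nonsense variants. Alternatives fold
  stop-retained variants with the silent bucket
  (`retained_with_no_change`) or with the stop-gain bucket
  (`retained_with_stop_gain`); stop-loss always counts as a
  different-group change.

The six-way classes themselves, and all per-residue/per-group
substitution tables, always use the strict five-way grouping —
the merge applies only to the headline same-vs-different tally.

Percentages are rounded half-up to one decimal (`decimal.Decimal`),
matching the usual reporting style; counts are exact integers.

## Sneath scoring

The Sneath index is an integer amino-acid dissimilarity in [5, 43]
(5 = Leu–Ile, the most alike pair; 43 = Pro–Glu and Pro–Arg). Variant
scoring extends it with two conventions: 0 for a synonymous change
(including stop→stop) and 100 when the variant is a stop codon. For
stop-loss (read-through) the score defaults to 100 as well — disrupting
termination is treated as severely as truncation — but is configurable
(`stop_loss_score`, restricted to {0} ∪ [5,43] ∪ {100}) so per-residue
mean scores can be recomputed under a milder reading. Mean scores per
original residue average over all 9 × (codon occurrences) records of
that residue, with the stop policy embedded at enumeration time.

### Matrix provenance — synthetic stand-in

Only five cells of the published Sneath table are available to this
package as exact anchors: Leu–Ile 5, Pro–Glu 43, Pro–Arg 43, Asp–Asn 14,
Ala–Pro 16. The packaged file `sneath_synthetic.tsv` is therefore a
**synthetic stand-in**: the remaining cells are synthesised from
standard physicochemical descriptors (Kyte–Doolittle hydropathy,
Zamyatnin residue volume, net side-chain charge, aromaticity,
Pro/Gly conformational flags, sulfur content, group membership) as a
weighted Euclidean distance, affinely mapped onto the 5–43 range and
rounded to integers, after which the five anchor cells are set to their
published values (`scripts/build_data_files.py` regenerates the file
deterministically). Consequences:

- every quantity that depends only on counts, classes, anchors or the
  0/100 conventions (partitions, substitution tables, frequency shifts,
  anchor scores) is unaffected;
- per-record scores and per-residue means for non-anchor pairs are
  stand-in values — plausible in scale and ordering, but not the
  published ones. Supplying a transcription of the original table via
  `load_matrix(path)` / `--matrix` substitutes the real values
  everywhere; the loader enforces symmetry, the 20-amino-acid cover,
  the 5–43 range and (by default) the five anchors, and accepts
  lower-triangular files by mirroring.

## Synthetic test sequences

`generate_random_cds(n_codons, seed)` emulates only the structural
contract of a CDS: ATG, then `n_codons − 2` codons drawn uniformly from
the 61 sense codons, then a uniformly chosen stop codon. Internal stops
are excluded by construction (no rejection sampling), so generation is
linear and seed-stable. It does not emulate codon-usage bias, GC
content, or any biological sequence composition: tests passing on these
sequences establish the combinatorial correctness of the enumeration
and classification (verified record-for-record against a brute-force
oracle that rebuilds each mutated full sequence and re-translates it
entirely), not distributional claims about real genes. Random CDSs of
up to 30 codons are used, which exercises every codon type with high
probability while keeping the suite fast.

## Numerical and degenerate-input choices

- All scores and counts are integers; means are the only floats.
- Minimal valid input is a 2-codon CDS ("ATG" + stop, 18 variants).
- An empty record list is an error for every aggregate (no silent NaNs).
- Querying a residue absent from the protein returns an empty table /
  empty position list, not an error.
- The pipeline validates before writing: an invalid sequence produces a
  nonzero exit and no partial output files.

## Known limitations

- Effects beyond the primary structure (secondary/tertiary/quaternary
  structure, stability, aggregation) are not modelled; the consequence
  classes and Sneath scores are primary-structure proxies only.
- Stop-loss elongation is flagged but the read-through peptide is not
  constructed.
- Non-anchor Sneath scores are synthetic (see above).
- Single CDS per invocation; batch processing is a shell loop.
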