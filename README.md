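# snpsat — exhaustive in-silico SNP saturation of a coding sequence

`snpsat` answers a simple question about a protein-coding gene: *if every
possible single-nucleotide substitution occurred, what would happen to the
protein?* For a CDS of length L it enumerates all 3L single-nucleotide
variants (three alternative bases at every position, mutated one at a time
against the original sequence), translates each variant codon under the
standard genetic code, classifies the consequence, and scores the chemical
severity of each amino-acid substitution.

It is aimed at protein biochemists and immunologists studying mutational
robustness of small, highly conserved proteins. The packaged worked example
is beta-2-microglobulin (B2M), the smallest immunoglobulin-domain protein:
a single 119-residue domain whose fold is pinned by one disulfide bond
(Cys45–Cys100), encoded by a 360-nt mature CDS.

## Model

Every variant codon is compared with its original codon and falls into
exactly one of six consequence classes:

| class | meaning |
|---|---|
| `SYNONYMOUS` | same amino acid (silent) |
| `SAME_GROUP_MISSENSE` | different amino acid, same physicochemical group |
| `CROSS_GROUP_MISSENSE` | different amino acid, different group |
| `NONSENSE` | sense codon → stop codon (truncation) |
| `STOP_RETAINED` | stop codon → a different stop codon |
| `STOP_LOSS` | stop codon → sense codon (read-through) |

The grouping partitions the 20 amino acids into five physicochemical
classes — positively charged {R,H,K}, negatively charged {D,E}, polar
{S,T,N,Q}, special {C,G,P} and hydrophobic {A,V,I,L,M,F,Y,W} — which under
the standard code are encoded by 10 / 4 / 14 / 10 / 23 codons (plus 3 stop
codons, totalling 64).

Each substitution is scored with the **Sneath chemical-dissimilarity
index**, an amino-acid pair dissimilarity derived from many physicochemical
properties, spanning 5 (Leu–Ile, the most alike pair) to 43 (Pro–Glu and
Pro–Arg). The index is extended with two conventions: **0** for a
synonymous change and **100** when a stop codon is involved, since a
truncation (or loss of termination) dwarfs any chemical change.
*Note:* the packaged matrix file is a synthetic stand-in — only the five
published anchor cells (Leu–Ile 5, Pro–Glu 43, Pro–Arg 43, Asp–Asn 14,
Ala–Pro 16) are exact; see `docs/methods.md`. Supply a transcription of the
original table via `--matrix` to use the real values throughout.

## Worked example

```sh
$ snpsat saturate --b2m --out out/
total SNPs: 1080
  no_change           239  (22.1%)
  same_group          274  (25.4%)
  stop_gain            57  (5.3%)
  different_group     510  (47.2%)
  no-or-minimal effect: 47.5%   major effect: 52.5%
tables written to .../out
```

The 360-nt B2M CDS yields 1080 variants: 239 (22.1%) are silent, 274
(25.4%) replace a residue with one of a similar chemical character, 57
(5.3%) create a premature stop codon, and 510 (47.2%) swap in a chemically
different residue. Folding these, about half of all possible SNPs (47.5%)
would leave the protein essentially unchanged while the other half (52.5%)
would alter it substantially — a picture of how exposed a conserved protein
is to random point mutation. (The "same group" tally here treats all
charged residues as one category, and the terminal stop codon's nine
variants count as "different group"; both conventions are switchable —
`--no-merge-charged`, `--stop-fold`.)

Per-residue substitution tables drill into critical sites, e.g. the two
disulfide-bond cysteines:

```sh
$ snpsat summarize --records out/snp_table.tsv --residue C
...
original residue C (18 SNPs)
  -> S  4
  -> *  2
  ...
```

Of the 18 SNPs hitting a Cys codon, only the 2 silent ones leave the
disulfide bond intact; two create a stop codon outright. The per-SNP table
(`out/snp_table.tsv`, one row per variant with position, codons, residues,
groups, consequence and Sneath score) makes this accounting explicit for
every residue.

The same analysis runs on any CDS (`--fasta file` or `--seq ATG...TAA`):
the input must start with ATG, be a multiple of 3, end with a stop codon
and contain no internal stop.

## Layout

- `src/snpsat/genetic_code.py` — standard code, residue grouping, codon accounting
- `src/snpsat/sneath.py` — dissimilarity matrix loading + extended scoring
- `src/snpsat/saturation.py` — CDS validation, translation, SNP enumeration, classification
- `src/snpsat/summaries.py` — partition, substitution tables, frequency shifts, mean scores
- `src/snpsat/io.py`, `src/snpsat/cli.py`, `src/snpsat/fixtures.py` — I/O, CLI, packaged data
- `docs/methods.md` — model conventions, data provenance, limitations
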