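# groupcons

Group-specific conservation analysis of protein-family alignments.

When a structural superfamily contains several enzyme families with
different functions — for example heme oxygenases, thiaminases, methane
monooxygenase hydroxylases and ribonucleotide reductase R2 proteins sharing
one fold — the interesting residues are often not the ones conserved across
the whole alignment but the ones conserved *within one family and nowhere
else*. `groupcons` finds both kinds from a single master multiple sequence
alignment:

- **Column conservation statistics** — per-column identity conservation
  (percent of sequences carrying the modal residue, gapped sequences in the
  denominator) and pooled similarity of physicochemical residue classes
  (aliphatic I/V/L/M, aromatic F/W/Y, acid-amide D/N), with census tables
  over configurable thresholds.
- **Group Entropy / Family Entropy scan** — for a user-defined partition of
  the sequences into groups, each column is scored with two Kullback–Leibler
  divergences: GE<sub>g</sub> = Σ<sub>a</sub> f<sub>g,a</sub>
  log₂(f<sub>g,a</sub>/r<sub>a</sub>), the divergence of group *g*'s
  pseudocounted residue distribution *f* from the complement groups'
  distribution *r*, and FE = Σ<sub>a</sub> F<sub>a</sub>
  log₂(F<sub>a</sub>/q<sub>a</sub>), the divergence of the family-wide
  distribution *F* from a background *q*. Group-specific sites have high GE
  and low FE (defaults: GE ≥ 10, FE ≤ 3); gap-dominated columns are
  excluded, never silently scored.
- **Conservation-estimator consensus** — six column scorers (Shannon
  entropy complement, property entropy, relative entropy, Jensen–Shannon
  divergence, von Neumann entropy, sum-of-pairs) swept over three background
  compositions (BLOSUM62, Swiss-Prot, Pfam) × seven BLOSUM matrices
  (35/40/45/50/62/80/100); a column counts as identified by a method only
  when it lands in the top 5% in **all 21** combinations.
- **Simplified evolutionary trace** — cut the UPGMA dendrogram into P
  subgroups and flag columns invariant inside every subgroup.
- **Phylogenetics** — gap-fraction trimming, maximum-likelihood pairwise
  distances under the Jones–Taylor–Thornton model, neighbor joining (exact
  on additive matrices), column bootstrap and strict majority-rule consensus
  with percent supports.
- **Motif scanning** — exact-match patterns with literals, `x` wildcards
  and `[..]` alternations; per-group presence fractions and alignment-index
  spans.
- **Synthetic benchmark generator** — grouped alignments with planted
  family-conserved, group-specific, class-conserved and background columns,
  plus gaps, fully reproducible from one seed, so every stage has a
  recovery-based test against known ground truth.

## Worked example

Generate the default synthetic benchmark (4 groups × 50 sequences, 500
columns, 10 group-specific sites per group at conservation 0.95, 5% gaps)
and scan it:

```python
from groupcons import SyntheticConfig, generate_alignment, GEntParams, gent_scan

config = SyntheticConfig(seed=1)
alignment, partition, truth = generate_alignment(config)
tables = gent_scan(alignment, partition, GEntParams())
print(tables["G1"].head(6)[["index", "group_entropy", "family_entropy",
                            "highest_group_residue", "selected"]])
```

```
 index  group_entropy  family_entropy highest_group_residue  selected
    37         11.071           1.180                   Val      True
   478         10.884           0.990                   Thr      True
   344         10.864           1.092                   Met      True
    36         10.863           1.518                   Arg      True
   151         10.736           0.909                   Phe      True
   168         10.580           1.189                   Gln      True
```

The six top-ranked columns are all planted group-specific sites of group G1
(the full planted set is {36, 37, 148, 151, 168, 232, 263, 344, 448, 478}):
each is strongly conserved inside G1 (GE ≈ 11 bits against the other three
groups) yet unremarkable family-wide (FE ≈ 1 bit). A family-invariant
column would instead show FE near log₂20 ≈ 4.3 and GE near 0.

The same analyses run from the shell:

```sh
groupcons simulate --seed 1 -o bench/
groupcons gent bench/alignment.fasta bench/groups.tsv -o gent_out/
groupcons run bench/alignment.fasta bench/groups.tsv -o report/   # full pipeline
```

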