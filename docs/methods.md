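# Methods

This note documents the models, conventions and numerical choices behind
`groupcons`, and what the synthetic benchmarks do and do not demonstrate.

## Alignment conventions

Columns are 1-based and reported 1-based everywhere. A residue is addressed
either by alignment index or, through `map_residue`, by its 1-based position
in the ungapped sequence, so a site can be written in the familiar
"His25{142}" style (residue 25 of a sequence sitting in alignment column
142). On input the gap dialects `.` and `~` are normalized to `-`, and the
ambiguity codes B, Z, J, U, O to `X`. `X` advances the residue number (it is
a real position in the protein) but carries no residue information, so every
counting and scoring routine treats it as a gap. Sequence ids must be unique;
duplicates are a hard error rather than a silent rename, because every
downstream table is keyed by id. MSF checksums are parsed but not verified.

## Conservation statistics

Identity conservation of a column is 100·n(modal)/N with N the full sequence
count, gapped sequences included. The gaps-in-denominator convention is
deliberate: a column that is leucine in 69% of sequences and gap or other
residues elsewhere is 69% conserved, which matches how conservation
percentages are usually quoted for family alignments with ragged coverage.
A non-gap-denominator variant can be obtained from the `ColumnProfile`
frequencies directly. Modal-residue ties break alphabetically; percentages
are computed exactly and rounded (nearest integer, ties away from zero) only
at reporting. Census bins (≥80, ≥60, [40,60)) are evaluated on unrounded
values. The similarity census reports columns reaching the threshold through
a pooled residue class only — columns already identity-conserved at the
threshold are excluded, so it lists *additional* positions. The default
classes are aliphatic {I,V,L,M}, aromatic {F,W,Y} and acid-amide {D,N};
tyrosine is included in the aromatic class (membership is configurable, and
borderline aromatic columns may shift between censuses if Y is dropped).

## Group Entropy / Family Entropy

Frequencies are pseudocounted Dirichlet-style: f_a = (n_a + β·q_a)/(N + β)
with β = 1 and uniform q by default, computed over non-gap cells only.
Group Entropy of group g is the KL divergence (bits) of g's distribution
from the distribution of all sequences *not* in g; Family Entropy is the KL
divergence of the family-wide distribution from the background q. The
original program this reconstructs did not publish its formula or scale, so
absolute printed scores from that program are not comparable; the default
thresholds (GE ≥ 10, FE ≤ 3) are kept as the conventional operating point
for groups of tens-to-hundreds of sequences, and a scale-free `top_k`
selection mode is provided. Note that GE is bounded by the pseudocounted
log-ratio, so very small groups (≲10 sequences) cannot reach GE = 10 with
β = 1: use `top_k` mode there.

Gap handling: a column is unscored for a group when the gap fraction within
the group or within its complement exceeds γ (default 0.5; γ = 0 gives the
strict any-gap-excludes rule). Unscored columns are absent from the output
table, never reported as 0. Per column the scan also reports the group's
modal residue and each other group's modal residue (three-letter codes), with
a second residue appended when it holds ≥ 25% of the group.

## Conservation estimators

All six estimators consume the column's non-gap frequency vector with a
pseudocount ε = 1e-6 (renormalized) and return bits, oriented so higher =
more conserved: log₂20 − H for Shannon, log₂K − H over K = 6 property
classes ({AVLIMC},{FWYH},{STNQ},{KR},{DE},{GP}) for property entropy, KL
and Jensen–Shannon divergence from the background, log₂20 − VN for von
Neumann entropy, and the mean pairwise similarity for sum-of-pairs. The
von Neumann density matrix is ρ = D·S·D/tr with D = diag(√p) and S a
similarity matrix; with S = I it reduces exactly to Shannon entropy, which
the tests verify to 1e-9. The similarity transform of a BLOSUM matrix
min-max normalizes the scores to [0,1], then divides by the geometric mean
of the two diagonal entries and clips at 1, giving a symmetric S with unit
diagonal. Columns with fewer than two non-gap residues get NaN and are
excluded from identification.

Gap penalization multiplies the raw score by the column's non-gap fraction
(switchable off). "Identified" means the top fraction φ of gap-adjusted
scores, as the largest set not exceeding φ (⌊φ·n⌋, at least 1), ties broken
toward the lower column index; φ = 0.05 by default. The consensus operation
intersects identified sets over all 3 backgrounds × 7 matrices; methods
insensitive to a parameter still run per combination so the semantics are
uniform. Backgrounds are the published BLOSUM62 marginal frequencies, the
Swiss-Prot release composition, and the Pfam-derived null composition used
by the HMMER suite, stored in `src/groupcons/data/backgrounds.json` and
renormalized to sum to 1. BLOSUM matrices come from biotite's bundled
standard tables.

## Evolutionary trace

The dendrogram is UPGMA (scipy average linkage) on the same JTT distance
matrix used for neighbor joining. A partition into P subgroups removes the
P−1 deepest merges; subgroup order (and any tie) is resolved by smallest
member name. A column is a trace column when every subgroup carries exactly
one residue; by default any gap in a subgroup breaks its invariance
(conservative), with an `ignore_gaps` mode that judges invariance over
non-gap members only. A trace column is group-specific when at least two
subgroups carry different residues. Finer partitions can both gain and lose
trace columns, so no monotonicity in P is asserted; the family-invariant
column set is contained in the trace set for every P, which is tested.

## Phylogenetics

Trimming removes columns whose gap fraction (gaps plus X) exceeds a
threshold, default 0.8, and returns the original→trimmed index map. Pairwise
distances are maximum-likelihood under the JTT amino-acid replacement model:
the rate matrix Q is built from the published Jones–Taylor–Thornton
exchangeabilities and equilibrium frequencies (bundled in
`src/groupcons/data/jtt.json`, converted from the standard PAML-format
table), normalized to one expected substitution per site per unit time; the
likelihood Σ_sites log[π_a P_ab(t)] over co-non-gap sites is maximized by
bounded scalar optimization on t ∈ [0, 10] with tolerance 1e-6, using the
spectral decomposition of the reversible Q for P(t). Distances are capped
at 10 because the surface flattens at saturation; sequence pairs at
observed mismatch above the model's saturation plateau (~0.94) will sit at
the cap and carry little signal — benchmarks should be designed away from
that regime (see below).

Neighbor joining is the standard Saitou–Nei algorithm with the Q criterion;
ties break toward the pair with the lexicographically smallest representative
leaf names, negative branch estimates are clamped to zero with the deficit
moved to the sister edge, and the final three nodes are joined with the
closed-form star lengths. On additive matrices the reconstruction is exact
to machine precision (tested against patristic distances and cross-checked
against scikit-bio's implementation). The column bootstrap draws replicate
r from a generator seeded (seed, r), so any replicate is reproducible in
isolation. Majority-rule consensus counts bipartitions oriented away from a
fixed reference taxon and keeps those present in strictly more than 50% of
trees — such splits are pairwise compatible and form a laminar family, from
which the consensus tree is assembled directly; supports are percentages on
internal nodes. PHYLIP-style extended (greedy) completion is deliberately
not the default.

## Motif scanning

Patterns are exact: literal residues, `x` matching any residue (including X,
never a gap), and `[..]` alternations over the 20 amino acids. Scanning
compiles to a lookahead regex so overlapping matches are all reported, and
is verified against a brute-force sliding-window oracle. Presence analysis
degaps each sequence, scans, and maps the first match back to alignment
indices; the reported span absorbs gap columns inside the motif, which is
why alignment spans can exceed the literal pattern length. No mismatch
tolerance or E-values: patterns are deterministic predicates.

## Synthetic benchmarks

The generator emulates a grouped family alignment with planted column
types; defaults are 4 groups × 50 sequences, 500 columns, 10
family-conserved columns, 10 group-specific columns per group, 5
class-conserved columns per similarity class, conservation c = 0.95, i.i.d.
gaps at 5%, background columns from column-specific Dirichlet(0.5)
compositions. Group-specific columns exclude the planted residue from the
other groups' background (sharp signal; a leak probability softens this).
Per-column substreams are derived from (seed, column), so columns are
reproducible in isolation. What the generator does *not* emulate:
phylogenetic correlation among sequences within a group (sequences are
conditionally i.i.d. given the column plan), correlated indel structure
beyond optional per-group gap blocks, and compositional drift between
groups. Passing recovery tests therefore demonstrates correctness of the
scoring machinery under the stated signal model, not performance on real
families with deep substructure.

Benchmark problem sizes were chosen to exercise each stage meaningfully at
interactive runtimes: the group-entropy benchmark uses the full default
generator; the estimator-consensus benchmark uses 5 invariant + 100
background columns with φ = 0.05 (so the identified set size equals the
planted count); the bootstrap benchmark uses 4 groups × 3 sequences over
400 columns with 280 family-conserved and 30 group-specific columns per
group at c = 1 and no gaps — strong family-wide conservation keeps
within-group distances near 0.1 substitutions/site, far below the
saturated high-variance regime, while the group-private columns separate
the clades by ~3× that distance, which is what "well-separated groups"
must mean in distance space for bootstrap supports to be stable at 100%.

## Known limitations

- The GE/FE scale depends on β and q; scores from other implementations are
  not directly comparable. Use rank-based selection when in doubt.
- JTT is the only substitution model offered for distances; no rate
  heterogeneity across sites.
- Consensus trees carry supports but no branch lengths.
- The pipeline assigns groups from a user-supplied table; mapping tree
  clades to group labels is left to the user.
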