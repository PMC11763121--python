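# Methods

## Segment model and scoring

Each fixed-length conserved segment type (K and its HKn(S) variant: 15
residues; H: 15; Y: 8; F: 10) is modelled by a per-position relative
frequency table over the 20 standard amino acids plus X.  Tables are built
from a segment library as

    freq[p][a] = (count of residue a at position p + c) / (n + 20 c)

with pseudocount `c` (default 0.01) and library size `n`.  Each position
normalizes to 1 over the 20 standard residues; the X column carries the
pseudocount floor and takes no part in normalization.  A candidate window is
scored by summing the frequency of its residue at every position, so scores
live in `[0, length]` and a consensus-perfect window under a peaked table
approaches the motif length.  This sum-of-frequencies score is the simplest
function consistent with the published threshold scales (6.0 on a 15-residue
K table, 3.5 on an 8-residue Y table).

The default tables are built from small bundled libraries containing the
published consensus sequences and their stated alternatives: the canonical K
segment, the HKn(S) variant, both Y forms (`TDEYGNPV`/`TDEYGNPI`), the first
ten residues of the F core `DRGLFDFLGKK`, and the twelve enumerations of
`M(A/S)GIIHKIEE(T/K/A)LH(I/M)G`.  The F table ships with the GC-variant
adjustment applied: the frequency of G at position 1 is copied from D, and
of C at position 2 from R, so GC-variant F segments (`GCGMFDFLKK`-like) are
detected in the same pass.  Users can override any table from their own
segment library file or a serialized TSV table.

Because the original segment libraries are not published, these
consensus-derived tables are much more peaked than tables estimated from
thousands of real segments.  Consequences: (i) absolute scores are not
comparable to scores from richer tables — only threshold-relative behaviour
is meaningful; (ii) near-consensus windows of one type can occasionally
cross another type's threshold.  The one known systematic case is a
canonical K segment followed immediately by glycine, whose one-shifted
window scores 7.2 on the H table (above the 6.8 H threshold): H and K
segments are related motifs, and with peaked tables eight coinciding
positions suffice.  The synthetic generator never emits such boundaries (see
below); on real data a richer user-supplied H library removes the artifact.

### S segments

S segments are variable-length serine tracts.  They are scored against a
three-block table — per-position frequencies for the first five residues,
one pooled frequency vector for all interior positions, and per-position
frequencies for the final two residues — with

    score = Σ first-5 + 3 × (mean interior) + Σ last-2,

a fixed `[0, 10]` scale regardless of segment length, compared against the
5.2 threshold.  Note that with a pooled interior only segments whose
interior is compositionally uniform can attain the ceiling of 10.

Scanning is seed-and-extend: every 5-residue window whose first-5 score
reaches half the S threshold seeds a candidate; the seed is anchored at its
first serine (an S segment is a serine tract, so leading non-serine residues
belong to the preceding phi); extension adds one residue at a time and stops
when the last two residues are both non-serine or at the C terminus.  A
terminating pair of acidic residues is retained — canonical S segments end
in Glu-Asp — while any other terminating pair is excluded.  Candidates
shorter than 7 residues or scoring below threshold are dropped.

## Scan order, masking and tie-breaks

Sequences are scanned for H, Y, F, S and K segments in that order, one
starting position at a time.  Within a type, above-threshold windows are
reduced to non-overlapping hits greedily: highest score first, leftmost
start on ties.  Scores are rounded to 9 decimals for this comparison so that
exact-arithmetic ties are not broken by floating-point noise.  Positions
claimed by an earlier-scanned type are masked for later types, so an
ambiguous region belongs to the earlier type.  The K scan applies the
canonical and variant tables together; each window keeps the better score
and records which table won.

## Classification

The ordered segment letters collapse to a structural formula (`Y3SK2`,
`HK2HK2`, ...).  Formula patterns map to groups: `K`→K1, `K+`→Kn, `SK+`→SKn,
`K+S`→KnS, `HK+(S)`→HKn/HKnS, `F+(S)K+`→FKn/FSKn, `Y+(S)K+`→YnKn/YnSKn;
anything else is irregular.  KnS and HKnS require the S hit to end within 10
residues of the C terminus (configurable); otherwise the arrangement is
irregular.  Irregular candidates are re-evaluated once with hits scoring
within 10% above their threshold ignored — an automated surrogate for the
original manual curation of low-scoring segments — and adopt a main-type
formula if one emerges.

Two screens follow.  A candidate in the K1/Kn/KnS/irregular groups whose
best K segment scores below 7.0 is demoted to pseudo-dehydrin.  A candidate
with a K hit starting within 60 residues of the N terminus, followed within
3 residues by a serine-dominated run (S/D/E residues, at least 4 serines,
serine majority), and lacking a terminal S segment, is classified as a
reticulon; the 60/3/4 operationalization of "near the N terminus" is a
package choice consistent with the published fused-segment example, and all
three values are configuration keys.  Orders follow the accessory segments:
F-containing groups → F(S)Kn, Y-containing → Yn(S)Kn, H-containing and KnS
→ (H)KnS; Kn (with K1 folded in after screening), SKn, pseudo and reticulon
remain unassigned; irregular sequences are placed by the accessory segments
they actually contain.

## Repeat families

Repeats are detected per seed length (6 and 10 by default).  All windows are
enumerated; windows whose Hamming identity reaches the floor
(`ceil(0.8 × L)`, i.e. 5/6 or 8/10 matches) are linked, and connected
components of this graph form clusters — exact all-pairs single linkage,
chosen over heuristic variants because it is order-independent and equals a
brute-force oracle by construction.  Within a cluster, overlapping windows
reduce left-to-right to a maximal non-overlapping set; the consensus is the
position-wise majority (ties alphabetical); copies below the identity floor
against the consensus are dropped; families need at least 3 copies.  A
repeat region seeds one cluster per alignment frame (windows shifted by one
link through their shared core), so families are reduced once more: best
frame first (copy count, then identity, then leftmost) and any family whose
copies overlap an already-kept family is suppressed.  Six-mer families fully
contained in ten-mer families are suppressed in reporting (verbose mode
keeps them).

`extend_family` grows all copies one residue per side while every copy stays
in bounds, no two copies collide, and the mean pairwise identity over the
grown span stays at or above the floor — an automated version of the
originally manual block extension (extension is off by default).
`annotate_repeat_segments` lists the conserved segments inside each copy;
offsets where at least half the copies carry a segment but one copy lacks it
become positionally inferred low-scoring segments, which the compound
formula grammar (`(Y3K)_8Y4(Y3)_2`-style) and segment counts can include.

## Phi statistics, composition, LDA

Phi segments are the complement of the segment hits; they tile each sequence
exactly.  The package reports: Y-Y gap lengths and sequences per group; His
counts in the up-to-6-residue prefix/suffix of every K segment (windows
truncate at the chain ends); Y-Y/S-K/K-S linkage profiles aligned at the
first residue after the N-terminal enclosing segment (up to 10 positions,
each populated position normalized to 1) with length histograms; a
three-domain parse of K-S linkers around the poly-K run (longest stretch
starting and ending in K, ≥3 residues, ≥⅔ lysine — the qualitative published
description operationalized, both parameters configurable); and C-terminal
distance classes (2–8, 9–16, 17–32, >32 residues after the last K) for
sequences without a terminal S segment.

Composition vectors are counts over the 20 standard residues divided by
their total; X residues are excluded from fractions and mass with a reported
count.  Molecular weight uses standard average residue masses (Biopython's
table) plus one water, in kDa.

LDA is the classical formulation: class means, pooled within-class
covariance with a ridge of 1e-6 on the diagonal (composition vectors lie on
a simplex, so the covariance is rank-deficient without it; one feature can
optionally be dropped instead), discriminant axes from the generalized
eigenproblem of between- versus within-class scatter, and Gaussian
equal-covariance discriminant scores with empirical priors.  Reported
accuracy is resubstitution; k-fold cross-validation is available as an
extension.  The implementation agrees with scikit-learn's
`LinearDiscriminantAnalysis` within 1% on held-out synthetic data (tested).

## Synthetic data

The generator assembles sequences from an initiator methionine, random phi
linkers and canonical segment realizations (the argmax of each default
table; H-containing architectures use the variant K consensus).  Default phi
composition is glycine 0.20, the nine polar residues sharing 0.60, the
remaining ten residues sharing 0.20 — the "rich in glycine and polar
residues" character of real phi segments.  Linker lengths default to 2–12
residues, except Y-Y gaps (1–2 residues, matching the close spacing of real
Y segments) and the terminal linker (0–3 after a terminal S so the S stays
terminal, otherwise 2–7).  Optional repeat planting inserts n copies of a
unit with random spacers.  Point substitutions are applied last, at a
per-residue rate, never touching the initiator.

Background linkers are sampled by rejection: a draw is discarded unless the
assembled sequence, scanned at mutation rate 0, yields exactly the planted
segments (hits inside planted repeat blocks excepted, since repeat units may
legitimately contain segments).  This makes the emitted ground truth the
*complete* truth — a Gly/polar-rich random background would otherwise
contain occasional chance Y windows (the 3.5/8 threshold is permissive) and
K+glycine boundary artifacts.  Planted-architecture recovery at mutation 0
is therefore exact by construction; what the recovery tests then measure is
the consistency of masking, ordering and formula generation, and — at
non-zero mutation rates — genuine robustness of scanning and classification.
What the generator does not emulate: indels, repeat-driven segment
proliferation phylogenies, length/composition heterogeneity across taxa, and
the weak, borderline-scoring segments that real curation has to adjudicate.
Passing synthetic tests shows algorithmic correctness under the modelled
architecture, not recall on the full diversity of real sequences.

## Problem sizes and numerical choices

The test suite verifies the scanner and repeat finder against exhaustive
brute-force oracles on 200 random sequences of up to 200 residues, formula
recovery on 204 mutation-free synthetic architectures, group assignment on a
400-sequence cohort at mutation rate 0.02 (≥95% required), and repeat-copy
recovery on 100 planted-repeat trials at mutation rate 0.05.  Determinism is
enforced throughout: a single integer seed drives every stochastic step, and
greedy selections use rounded-score, leftmost-first tie-breaks.

## Known limitations

* Default tables are consensus-derived and peaked; absolute scores are not
  comparable to richer user-supplied tables, and rare cross-type threshold
  crossings (K+G vs the H table) exist at type boundaries.
* The manual curation steps of the original workflow (irregular
  reclassification, repeat parsing, reticulon confirmation against the
  C-terminal homology domain) are approximated by documented automatic
  rules, not reproduced.
* Database-scale statistics (group proportions across land-plant lineages,
  GC-variant counts) depend on a sequence harvest that is outside the scope
  of this package; the package computes them for whatever input it is given.
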