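# dhnscan

Scanning, classification and repeat analysis of **dehydrins** (Dhns) —
intrinsically disordered plant proteins closely associated with tolerance of
dehydration, freezing and other dehydrative stresses.

Dehydrins are defined by short conserved motifs embedded in highly variable,
glycine/polar-rich disordered linkers ("phi segments"):

| segment | length | consensus | role |
|---------|--------|-----------|------|
| K  | 15 | `EKKGIMDKIKEKLPG` | diagnostic; amphipathic helix, membrane binding |
| K (HKnS variant) | 15 | `HKEGFVDKIKDKIHG` | the K form typical of (H)KnS dehydrins |
| Y  | 8  | `TDEYGNP(V/I)` | N-terminal, usually in closely spaced multiples |
| F  | 10 | `DRGLFDFLGK(K)` | single copy N-terminal to K segments |
| H  | 15 | `M(A/S)GIIHKIEE(T/K/A)LH(I/M)G` | N-terminus of dehydrins with a terminal S |
| S  | variable | serine tract, single D/E interruptions, ends Glu-Asp | phosphorylatable |

`dhnscan` locates these segments with per-position residue frequency tables
(score of a window = Σ per-position relative frequencies, range
`[0, length]`), assembles a structural formula such as `Y3SK2`, classifies
each sequence into one of thirteen groups (K1, Kn, SKn, KnS, HKn, HKnS, FKn,
FSKn, YnKn, YnSKn, irregular, pseudo, reticulon) and maps the groups onto
the three phylogenetically defined orders F(S)Kn, Yn(S)Kn and (H)KnS.
Candidates whose best K segment scores below 7.0 in the K-only groups are
screened out as pseudo-dehydrins; proteins with a fused K+serine-run segment
near the N terminus and no terminal S segment are screened out as
reticulons.  Beyond scanning, the package detects internal repeat families
(6/10-residue seeds, ≥80% identity, ≥3 copies), computes phi-linker
statistics (Y-Y spacing, S-K/K-S linkage profiles, His flanks of K segments,
C-terminal distance classes, composition and molecular weight), fits linear
discriminant analysis on amino-acid composition, and generates synthetic
dehydrin-like cohorts with exact ground truth.

## Worked example

`examples/scan_architecture.py` builds a toy Y2SK2 dehydrin from the
consensus segments and scans it:

```
sequence length: 85 residues
located segments (1-based coordinates):
   Y    7-14  score  6.85  TDEYGNPV
   Y   17-24  score  6.85  TDEYGNPV
   S   30-41  score  9.15  SSSSSSSSSSED
   K   48-62  score 12.62  EKKGIMDKIKEKLPG
   K   67-81  score 12.62  EKKGIMDKIKEKLPG
structural formula : Y2SK2
group / order      : YnSKn / Yn(S)Kn
best K-segment score 12.62 (>= 7.0, so not a pseudo-dehydrin)
```

Each score is the sum of per-position frequencies under that segment's
table, so a perfect consensus match under a peaked table approaches the
motif length; the acceptance thresholds are 6.0 (K), 6.8 (H), 5.0 (F),
3.5 (Y) and 5.2 (S, on a fixed 0–10 scale).  The other examples cover
repeat detection (`detect_repeats.py`), phi statistics
(`phi_statistics.py`) and LDA on composition (`composition_lda.py`).

## Command line

```sh
dhnscan scan input.fasta -o out/        # dhn_types/segments/repeat_summary/repeats .tsv
dhnscan stats input.fasta -o out/       # composition, Y-Y spacing, His flanks, linkages
dhnscan lda out/composition.tsv -o lda/ # LD scores + confusion matrix
dhnscan simulate -n 100 --seed 1 -o sim/
```

Every run echoes its fully resolved configuration (`config_used.txt`) and
logs the candidate funnel (candidates → K-passing → screened → confirmed)
to stderr.

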