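"""Scan a small dehydrin-like protein and print its architecture.

Builds a toy Y2SK2 sequence from published consensus segments joined by
hand-written phi linkers, scans it with the default frequency tables, and
prints each located segment with its conservation score, the structural
formula, and the group/order classification.
"""

from dhnscan import RunConfig, classify, default_tables, scan_sequence

sequence = (
    "M" + "GGTSN"
    + "TDEYGNPV" + "RG" + "TDEYGNPV"          # two closely spaced Y segments
    + "GGSTQ" + "SSSSSSSSSSED"                 # serine tract ending Glu-Asp
    + "DGQGGR"                                 # conserved S-K linker
    + "EKKGIMDKIKEKLPG" + "THNQ" + "EKKGIMDKIKEKLPG"  # two K segments
    + "HHGG"
)

config = RunConfig()
tables = default_tables()
architecture = scan_sequence(sequence, tables, config)

print(f"sequence length: {len(sequence)} residues")
print("located segments (1-based coordinates):")
for hit in architecture.hits:
    print(
        f"  {hit.segment_type:>2}  {hit.start + 1:>3}-{hit.end:<3} "
        f"score {hit.score:5.2f}  {hit.sequence}"
    )

classification = classify(architecture, config)
print(f"structural formula : {architecture.formula}")
print(f"group / order      : {classification.group} / {classification.order}")
print(f"best K-segment score {classification.max_k_score:.2f} "
      "(>= 7.0, so not a pseudo-dehydrin)")
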