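"""Cohort statistics on phi linkers: Y-Y spacing, His flanks, C-terminal
distance classes.

Generates a synthetic cohort with the default group mix, scans and
classifies every sequence, and prints the descriptive statistics computed on
the regions between conserved segments.
"""

from collections import Counter

from dhnscan import (
    RunConfig,
    classify,
    cterm_distance_classes,
    default_tables,
    generate_cohort,
    his_flank_summary,
    his_flank_tally,
    scan_sequence,
    yy_spacing,
)
from dhnscan.classify import fold_k1

config = RunConfig()
tables = default_tables()
records, truth = generate_cohort(150, seed=42, mutation_rate=0.02)

items = []
tallies = []
for record in records:
    arch = scan_sequence(record.sequence, tables, config)
    cls = classify(arch, config)
    if cls is None or cls.group in ("pseudo", "reticulon"):
        continue
    items.append((fold_k1(cls.group), arch))
    tallies.append(his_flank_tally(record.sequence, arch.hits_of("K")))

print(f"confirmed sequences: {len(items)}")

gaps = yy_spacing(items)
print(f"\nY-Y linkages: {len(gaps)}")
print("gap-length counts:", dict(Counter(gaps["gap_length"])))
print("(multiple Y segments sit one or two residues apart)")

import pandas as pd

flanks = pd.concat(tallies, ignore_index=True)
summary = his_flank_summary(flanks)
print(f"\nK segments tallied: {summary['n']}")
print(f"fraction with >=1 flanking His: {summary['ge1']:.2f}, "
      f">=2: {summary['ge2']:.2f}")

classes = cterm_distance_classes(items)
print("\nC-terminal distance of the last K segment "
      "(sequences without terminal S):")
print(classes["class"].value_counts().to_string())
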