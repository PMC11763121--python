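"""Find internal repeat families and extend them to maximal blocks.

Plants four copies of a short Glu/Lys-rich unit in a synthetic K1 dehydrin,
then runs seed-based repeat detection (10-residue windows, 80% identity,
at least 3 copies) and block extension, printing family coordinates and
consensus — the kind of internal duplication that drives dehydrin
diversification.
"""

from dhnscan import RepeatPlant, SyntheticSpec, extend_family, find_repeats, generate

spec = SyntheticSpec(
    architecture=["K"],
    repeat_plant=RepeatPlant("GYHKEEPKWA", copies=4),
    mutation_rate=0.03,
    seed=11,
)
record, truth = generate(spec)
print(f"synthetic sequence ({len(record.sequence)} residues):")
print(record.sequence)
print(f"planted copies at {truth.repeat_copies}")

families = find_repeats(record.sequence, seed_length=10)
for i, family in enumerate(families, 1):
    print(f"family {i}: {family.copy_count} copies, "
          f"consensus {family.consensus}, "
          f"min identity {family.min_pairwise_identity:.2f}")
    for (start, end), copy_seq in zip(family.copies, family.copy_seqs):
        print(f"  {start + 1:>3}-{end:<3} {copy_seq}")
    extended = extend_family(record.sequence, family)
    grown = extended.copies[0][1] - extended.copies[0][0]
    print(f"  after extension: copies grow to {grown} residues each")
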