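"""Repeat family detection, extension and segment annotation."""

import numpy as np
import pytest

import oracles
from dhnscan.repeats import (
    RepeatFamily,
    annotate_repeat_segments,
    compound_formula,
    extend_family,
    find_all_repeats,
    find_repeats,
    hits_with_inferred,
    identity,
)
from dhnscan.scanner import scan_sequence
from dhnscan.synthetic import RepeatPlant, SyntheticSpec, generate

UNIT = "GYHKEEPKAA"  # published Carpinus repeat consensus core


class TestFindRepeats:
    def test_three_exact_copies_one_family(self):
        seq = "M" + UNIT + "TTTTT" + UNIT + "NNNNN" + UNIT + "QQQQ"
        fams = find_repeats(seq, 10)
        assert len(fams) == 1
        fam = fams[0]
        assert fam.copy_count == 3
        assert fam.consensus == UNIT
        assert fam.min_pairwise_identity == 1.0

    def test_two_copies_do_not_form_a_family(self):
        seq = UNIT + "TTTTT" + UNIT
        assert find_repeats(seq, 10) == []

    def test_eighty_percent_identity_copy_retained(self):
        degraded = "GYHKAAPKAA"  # 8/10 matches to the consensus
        seq = UNIT + "TTTTT" + UNIT + "NNNNN" + degraded + "QQQQ"
        fams = find_repeats(seq, 10)
        assert len(fams) == 1
        assert fams[0].copy_count == 3
        assert fams[0].min_pairwise_identity == pytest.approx(0.8)

    def test_below_identity_floor_excluded(self):
        too_far = "GYWWAAPKAA"  # 6/10 matches
        seq = UNIT + "TTTTT" + UNIT + "NNNNN" + too_far
        assert find_repeats(seq, 10) == []

    def test_sixmer_seeds(self):
        seq = "M" + "KEKEKP" + "TTTTT" + "KEKEKP" + "NNNNN" + "KEKEKP"
        fams = find_repeats(seq, 6)
        assert len(fams) == 1 and fams[0].copy_count == 3

    def test_copies_never_overlap_and_satisfy_identity(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            seq = oracles.random_dhn_like(rng, max_len=150)
            for seed_len in (6, 10):
                for fam in find_repeats(seq, seed_len):
                    for a, b in zip(fam.copies, fam.copies[1:]):
                        assert a[1] <= b[0]
                    for copy_seq in fam.copy_seqs:
                        assert identity(copy_seq, fam.consensus) >= 0.8

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(32)
        for _ in range(25):
            seq = oracles.random_dhn_like(rng, max_len=150)
            for seed_len in (6, 10):
                got = [
                    (tuple(f.copies), f.consensus)
                    for f in find_repeats(seq, seed_len)
                ]
                assert got == oracles.oracle_repeats(seq, seed_len)

    @pytest.mark.parametrize("block", range(4))
    def test_planted_copies_recovered_under_mutation(self, block):
        """Every planted copy still within the 80% identity floor after
        mutation is recovered (possibly in a shifted alignment frame)."""
        unit = "GYHKEEPKWA"
        for seed in range(block * 25, block * 25 + 25):
            rng = np.random.default_rng(1000 + seed)
            n_copies = int(rng.integers(3, 11))
            spec = SyntheticSpec(
                architecture=["K"],
                repeat_plant=RepeatPlant(unit, n_copies),
                mutation_rate=0.05,
                seed=seed,
            )
            record, truth = generate(spec)
            recoverable = sum(
                1 for s, e in truth.repeat_copies
                if sum(a == b for a, b in zip(record.sequence[s:e], unit)) >= 8
            )
            fams = [
                f for f in find_repeats(record.sequence, 10)
                if any(
                    s < pe and ps < e
                    for s, e in f.copies
                    for ps, pe in truth.repeat_copies
                )
            ]
            best = max((f.copy_count for f in fams), default=0)
            assert best >= max(recoverable, 3), (
                f"seed {seed}: recovered {best} of {recoverable} "
                f"recoverable copies ({n_copies} planted)"
            )
            assert best <= n_copies + 1


class TestSuppression:
    def test_contained_sixmer_families_suppressed(self):
        seq = "M" + UNIT + "TTTTT" + UNIT + "NNNNN" + UNIT + "QQQQ"
        fams = find_all_repeats(seq, (6, 10))
        assert {f.seed_length for f in fams} == {10}
        verbose = find_all_repeats(seq, (6, 10), verbose=True)
        assert len(verbose) >= len(fams)


class TestExtension:
    def test_tandem_exact_copies_extend_to_full_unit(self):
        unit = "GYHKEEPKAAQSTNWEDFRMCLIVGHWEEP"
        seq = unit * 3 + "GGGG"
        fam = find_repeats(seq, 10)[0]
        extended = extend_family(seq, fam)
        assert extended.extended
        assert extended.copies == [(0, 30), (30, 60), (60, 90)]

    def test_adjacent_copies_returned_unchanged(self):
        seq = "SSSSS" + "ABCDEFGHIJ" * 3 + "SSSSS".replace("B", "")
        seq = "TTTTT" + "GYHKEEPKAA" * 3 + "TTTTT"
        fam = find_repeats(seq, 10)[0]
        before = list(fam.copies)
        extended = extend_family(seq, fam)
        # copies are tandem: growth on either side would collide
        assert [
            (e - s) for s, e in extended.copies
        ] == [(e - s) for s, e in before]

    def test_extension_halts_at_divergent_spacers(self):
        core = "GYHKEEPKAA"
        seq = (
            "M" + "WWWWCIVMFA" + core + "LIVMFWYCAQ"
            + "NHQDERSTGA" + core + "AGTSREDQHN"
            + "FMVILCWYAQ" + core + "QAYWCLIFMV"
        )
        fam = find_repeats(seq, 10)[0]
        extended = extend_family(seq, fam)
        grown = extended.copies[0][1] - extended.copies[0][0]
        assert grown < 20  # flanks are mutually dissimilar


class TestAnnotation:
    def _family_sequence(self):
        # three identical copies, each containing one Y and one K segment
        copy = "TDEYGNPV" + "RG" + "EKKGIMDKIKEKLPG" + "TQ"
        seq = "M" + "TTNQ" + copy * 3 + "TTHH"
        copies = [(5 + i * len(copy), 5 + (i + 1) * len(copy))
                  for i in range(3)]
        return seq, copies, copy

    def test_copy_formulas_reported(self, tables, cfg):
        seq, copies, copy = self._family_sequence()
        arch = scan_sequence(seq, tables, cfg)
        fam = RepeatFamily(
            seed_length=10,
            copies=copies,
            copy_seqs=[seq[s:e] for s, e in copies],
            consensus=copy,
            min_pairwise_identity=1.0,
        )
        annotations = annotate_repeat_segments(fam, arch)
        assert [a.formula for a in annotations] == ["YK", "YK", "YK"]
        assert all(a.inferred_sites == [] for a in annotations)

    def test_missing_segment_inferred_by_position(self, tables, cfg):
        seq, copies, copy = self._family_sequence()
        # degrade the K segment of the middle copy beyond recognition
        start = copies[1][0] + 10
        seq = seq[:start] + "TQNHGSTQNHGSTQN" + seq[start + 15:]
        arch = scan_sequence(seq, tables, cfg)
        fam = RepeatFamily(
            seed_length=10, copies=copies,
            copy_seqs=[seq[s:e] for s, e in copies],
            consensus=copy, min_pairwise_identity=0.8,
        )
        annotations = annotate_repeat_segments(fam, arch)
        assert annotations[1].inferred_sites == [("K", start)]
        augmented = hits_with_inferred(arch, [fam])
        k_hits = [h for h in augmented if h.segment_type == "K"]
        assert len(k_hits) == 3
        assert sum(h.inferred for h in k_hits) == 1

    def test_phi_only_family_has_empty_annotations(self, tables, cfg):
        seq = "M" + "TTNQ" + (UNIT + "TTTTT") * 3 + "EKKGIMDKIKEKLPG" + "TT"
        arch = scan_sequence(seq, tables, cfg)
        fam = find_repeats(seq, 10)[0]
        annotations = annotate_repeat_segments(fam, arch)
        assert all(a.formula == "" for a in annotations)


class TestCompoundFormula:
    def test_repeat_blocks_collapse_with_counts(self, tables, cfg):
        copy = "TDEYGNPV" + "RG" + "EKKGIMDKIKEKLPG" + "TQ"
        seq = "M" + "TTNQ" + copy * 3 + "TTHH"
        arch = scan_sequence(seq, tables, cfg)
        copies = [(5 + i * len(copy), 5 + (i + 1) * len(copy))
                  for i in range(3)]
        assert compound_formula(arch.hits, copies) == "(YK)_3"

    def test_plain_hits_outside_copies_use_plain_grammar(self, tables, cfg):
        copy = "TDEYGNPV" + "RG" + "EKKGIMDKIKEKLPG" + "TQ"
        tail = "TDEYGNPV" + "RG" + "TDEYGNPV"
        seq = "M" + "TTNQ" + copy * 2 + tail + "TTHH"
        arch = scan_sequence(seq, tables, cfg)
        copies = [(5 + i * len(copy), 5 + (i + 1) * len(copy))
                  for i in range(2)]
        assert compound_formula(arch.hits, copies) == "(YK)_2Y2"
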