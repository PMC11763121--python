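"""Frequency-table construction and window scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dhnscan.scoring import (
    AA20,
    AA_INDEX,
    LibraryError,
    apply_gc_variant,
    build_s_table,
    build_table,
    bundled_library,
    default_tables,
    read_table,
    score_s_segment,
    score_window,
    write_table,
)

K_CONSENSUS = "EKKGIMDKIKEKLPG"


class TestBuildTable:
    def test_degenerate_library_gives_unit_frequencies(self):
        table = build_table([K_CONSENSUS] * 4, "K", pseudocount=0.0)
        assert table.freqs[0, AA_INDEX["E"]] == 1.0
        assert table.freqs[0, AA_INDEX["A"]] == 0.0
        assert table.library_size == 4

    def test_split_position_frequencies(self):
        lib = [K_CONSENSUS, "H" + K_CONSENSUS[1:]]
        table = build_table(lib, "K", pseudocount=0.0)
        assert table.freqs[0, AA_INDEX["E"]] == pytest.approx(0.5)
        assert table.freqs[0, AA_INDEX["H"]] == pytest.approx(0.5)

    def test_counting_matches_naive_tally(self):
        rng = np.random.default_rng(11)
        lib = [
            "".join(rng.choice(list(AA20), size=15)) for _ in range(10)
        ]
        table = build_table(lib, "K", pseudocount=0.5)
        # independent per-position tally
        for p in range(15):
            for aa in AA20:
                count = sum(1 for s in lib if s[p] == aa)
                expected = (count + 0.5) / (10 + 20 * 0.5)
                assert table.freqs[p, AA_INDEX[aa]] == pytest.approx(expected)

    def test_rows_normalize_over_standard_residues(self):
        table = build_table(bundled_library("H"), "H", pseudocount=0.01)
        sums = table.freqs[:, :20].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    @pytest.mark.parametrize("bad_lib", [[], ["EKKGIMDKIKEKLP"]])
    def test_invalid_libraries_rejected(self, bad_lib):
        with pytest.raises(LibraryError):
            build_table(bad_lib, "K")

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.text(alphabet=AA20, min_size=8, max_size=8),
            min_size=1, max_size=8,
        )
    )
    def test_random_libraries_match_counting_oracle(self, lib):
        table = build_table(lib, "Y", pseudocount=0.0)
        for p in range(8):
            for aa in set(s[p] for s in lib):
                count = sum(1 for s in lib if s[p] == aa)
                assert table.freqs[p, AA_INDEX[aa]] == pytest.approx(
                    count / len(lib)
                )


class TestSTable:
    def test_single_entry_blocks(self):
        table = build_s_table(["SSSSSDSSED"], pseudocount=0.0)
        assert all(
            table.first5[p, AA_INDEX["S"]] == 1.0 for p in range(5)
        )
        assert table.last2[0, AA_INDEX["E"]] == 1.0
        assert table.last2[1, AA_INDEX["D"]] == 1.0
        # interior pooled over "DSS"
        assert table.interior[AA_INDEX["S"]] == pytest.approx(2 / 3)
        assert table.interior[AA_INDEX["D"]] == pytest.approx(1 / 3)

    def test_interior_pooling_across_lengths(self):
        # lengths 8 and 12 pool (8-7) + (12-7) = 6 interior positions
        table = build_s_table(["SSSSSSED", "SSSSSDDDDSED"], pseudocount=0.0)
        # entry 1 interior: "S"; entry 2 interior: "DDDDS"
        assert table.interior[AA_INDEX["S"]] == pytest.approx(2 / 6)
        assert table.interior[AA_INDEX["D"]] == pytest.approx(4 / 6)

    def test_short_entries_rejected(self):
        with pytest.raises(LibraryError):
            build_s_table(["SSSSED"])
        with pytest.raises(LibraryError):
            build_s_table([])

    def test_self_scoring_reaches_maximum_for_uniform_interior(self):
        # with a pooled interior block, only a segment whose interior is
        # compositionally uniform can attain the ceiling of 10
        table = build_s_table(["SSSSSSSSED"], pseudocount=0.0)
        assert score_s_segment("SSSSSSSSED", 0, 10, table) == pytest.approx(10.0)
        mixed = build_s_table(["SSSSSDSSED"], pseudocount=0.0)
        assert score_s_segment("SSSSSDSSED", 0, 10, mixed) < 10.0

    def test_score_decomposes_into_blocks(self, tables):
        seg = "SSSSTSDSSSED"
        table = tables["S"]
        total = score_s_segment(seg, 0, len(seg), table)
        first5 = sum(table.first5[p, AA_INDEX[seg[p]]] for p in range(5))
        inner = seg[5:-2]
        interior = 3 * sum(table.interior[AA_INDEX[c]] for c in inner) / len(inner)
        last2 = (
            table.last2[0, AA_INDEX[seg[-2]]]
            + table.last2[1, AA_INDEX[seg[-1]]]
        )
        assert total == pytest.approx(first5 + interior + last2)

    def test_too_short_segment_errors(self, tables):
        with pytest.raises(ValueError):
            score_s_segment("SSSSSD", 0, 6, tables["S"])


class TestGcVariant:
    def test_donor_cells_copied(self):
        table = build_table(["DRGLFDFLGK"], "F", pseudocount=0.0)
        adjusted = apply_gc_variant(table)
        assert adjusted.freqs[0, AA_INDEX["G"]] == table.freqs[0, AA_INDEX["D"]]
        assert adjusted.freqs[1, AA_INDEX["C"]] == table.freqs[1, AA_INDEX["R"]]
        other = np.ones(adjusted.freqs.shape, dtype=bool)
        other[0, AA_INDEX["G"]] = other[1, AA_INDEX["C"]] = False
        assert np.array_equal(adjusted.freqs[other], table.freqs[other])

    def test_idempotent(self):
        table = apply_gc_variant(build_table(["DRGLFDFLGK"], "F"))
        again = apply_gc_variant(table)
        assert np.array_equal(table.freqs, again.freqs)

    def test_gc_variant_window_scores_higher_after_adjustment(self):
        plain = default_tables(gc_variant=False)["F"]
        adjusted = apply_gc_variant(plain)
        window = "GCGMFDFLKK"  # the published GC-variant F segment
        assert score_window(window, 0, adjusted) > score_window(window, 0, plain)

    def test_rejects_non_f_tables(self):
        with pytest.raises(ValueError):
            apply_gc_variant(build_table([K_CONSENSUS], "K"))


class TestScoreWindow:
    def test_consensus_passes_threshold(self, tables):
        assert score_window(K_CONSENSUS, 0, tables["K"]) >= 6.0

    def test_unrelated_window_scores_zero_without_pseudocount(self):
        table = build_table([K_CONSENSUS], "K", pseudocount=0.0)
        assert score_window("A" * 15, 0, table) == 0.0

    def test_matches_per_position_summation(self, tables):
        window = "EKKGIMDKIKEKLPA"  # one substitution at the last position
        table = tables["K"]
        expected = sum(
            table.freqs[p, AA_INDEX[window[p]]] for p in range(15)
        )
        assert score_window(window, 0, table) == pytest.approx(expected)

    def test_out_of_bounds_errors(self, tables):
        with pytest.raises(IndexError):
            score_window("MAG", 0, tables["K"])

    def test_consensus_maximality(self):
        table = build_table([K_CONSENSUS], "K", pseudocount=0.0)
        assert score_window(K_CONSENSUS, 0, table) == pytest.approx(15.0)
        rng = np.random.default_rng(3)
        for _ in range(50):
            variant = list(K_CONSENSUS)
            pos = int(rng.integers(0, 15))
            variant[pos] = str(
                rng.choice([a for a in AA20 if a != K_CONSENSUS[pos]])
            )
            assert score_window("".join(variant), 0, table) < 15.0

    def test_monotone_degradation(self, tables):
        table = tables["K"]
        rng = np.random.default_rng(4)
        for _ in range(50):
            window = list(K_CONSENSUS)
            pos = int(rng.integers(0, 15))
            current = table.freqs[pos, AA_INDEX[window[pos]]]
            lower = [a for a in AA20 if table.freqs[pos, AA_INDEX[a]] <= current]
            window[pos] = str(rng.choice(lower))
            assert score_window("".join(window), 0, table) <= score_window(
                K_CONSENSUS, 0, table
            ) + 1e-12

    @settings(max_examples=40, deadline=None)
    @given(st.text(alphabet=AA20 + "X", min_size=15, max_size=15))
    def test_scores_stay_within_bounds(self, window):
        score = score_window(window, 0, default_tables()["K"])
        assert 0.0 <= score <= 15.0


class TestSerialization:
    def test_round_trip_fixed_table(self, tables, tmp_path):
        path = tmp_path / "k.tsv"
        write_table(tables["K"], path)
        loaded = read_table(path)
        assert loaded.segment_type == "K"
        assert loaded.library_size == tables["K"].library_size
        assert np.array_equal(loaded.freqs, tables["K"].freqs)

    def test_round_trip_s_table(self, tables, tmp_path):
        path = tmp_path / "s.tsv"
        write_table(tables["S"], path)
        loaded = read_table(path)
        assert np.array_equal(loaded.first5, tables["S"].first5)
        assert np.array_equal(loaded.interior, tables["S"].interior)
        assert np.array_equal(loaded.last2, tables["S"].last2)
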