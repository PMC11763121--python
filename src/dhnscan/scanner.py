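"""Sliding-window segment scanning and structural-formula construction.

Each protein is scanned for H, Y, F, S and K segments in that fixed order,
one starting position at a time.  Within a type, above-threshold windows are
reduced to non-overlapping hits greedily (highest score first, leftmost on
ties); positions claimed by an earlier-scanned type are masked for later
types.  The K scan applies both the canonical and the HKn(S)-variant tables
and keeps the better score per window.

The ordered hits yield a structural formula in the HFYnSKnS style, e.g.
``Y3SK2`` for three Y segments, one S and two K segments in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import RunConfig
from .scoring import (
    FrequencyTable,
    STable,
    default_tables,
    score_s_first5,
    score_s_segment,
    score_window,
)

_ACIDIC = frozenset("DE")


@dataclass
class SegmentHit:
    """One located conserved segment (0-based half-open interval)."""

    segment_type: str
    start: int
    end: int
    score: float
    sequence: str
    k_variant: bool = False
    #: True for low-scoring segments inferred by position within repeat
    #: copies rather than found by the scanner.
    inferred: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "SegmentHit") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class PhiSegment:
    """A disordered linker between, before or after conserved segments."""

    kind: str  # "N-terminal", "C-terminal" or e.g. "Y-Y", "S-K"
    start: int
    end: int
    sequence: str


@dataclass
class Architecture:
    """Ordered, non-overlapping segment hits for one sequence."""

    sequence: str
    hits: list[SegmentHit] = field(default_factory=list)

    @property
    def formula(self) -> str:
        return formula_of(self.hits)

    def hits_of(self, segment_type: str) -> list[SegmentHit]:
        return [h for h in self.hits if h.segment_type == segment_type]

    def phi_segments(self) -> list[PhiSegment]:
        """Complement intervals tiling the sequence around the hits."""
        out: list[PhiSegment] = []
        prev_end = 0
        prev_type: str | None = None
        for hit in self.hits:
            if hit.start > prev_end:
                kind = "N-terminal" if prev_type is None else (
                    f"{prev_type}-{hit.segment_type}"
                )
                out.append(
                    PhiSegment(kind, prev_end, hit.start,
                               self.sequence[prev_end:hit.start])
                )
            prev_end = hit.end
            prev_type = hit.segment_type
        if prev_end < len(self.sequence):
            kind = "N-terminal" if prev_type is None else "C-terminal"
            out.append(
                PhiSegment(kind, prev_end, len(self.sequence),
                           self.sequence[prev_end:])
            )
        return out

    def phi_before(self, hit: SegmentHit) -> str:
        """The phi sequence immediately preceding a hit (may be empty)."""
        idx = self.hits.index(hit)
        prev_end = self.hits[idx - 1].end if idx > 0 else 0
        return self.sequence[prev_end:hit.start]


def formula_of(hits: Sequence[SegmentHit]) -> str:
    """Collapse ordered segment letters into an HFYnSKnS-style formula."""
    letters = [h.segment_type for h in hits]
    parts = []
    for letter, run in groupby(letters):
        n = len(list(run))
        parts.append(letter if n == 1 else f"{letter}{n}")
    return "".join(parts)


def _select_greedy(
    candidates: list[tuple[float, int, int]], taken: np.ndarray
) -> list[tuple[float, int, int]]:
    """Pick non-overlapping candidates by descending score, leftmost on ties.

    ``candidates`` are (score, start, end); ``taken`` is a boolean mask of
    positions already claimed (updated in place).
    """
    chosen = []
    # round scores so exact-arithmetic ties are not broken by float noise
    for score, start, end in sorted(
        candidates, key=lambda c: (-round(c[0], 9), c[1])
    ):
        if not taken[start:end].any():
            taken[start:end] = True
            chosen.append((score, start, end))
    return sorted(chosen, key=lambda c: c[1])


def scan_fixed(
    sequence: str,
    table: FrequencyTable,
    threshold: float,
    mask: np.ndarray | None = None,
    variant_table: FrequencyTable | None = None,
) -> list[SegmentHit]:
    """Scan with a fixed-length table; return non-overlapping hits.

    When ``variant_table`` is given (the dual-K scan), each window takes the
    higher of the two table scores and the hit records which table won.
    """
    n = len(sequence)
    length = table.length
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    candidates: list[tuple[float, int, int]] = []
    variant_flags: dict[int, bool] = {}
    for start in range(n - length + 1):
        if mask[start:start + length].any():
            continue
        score = score_window(sequence, start, table)
        is_variant = False
        if variant_table is not None:
            vscore = score_window(sequence, start, variant_table)
            if vscore > score:
                score, is_variant = vscore, True
        if score >= threshold:
            candidates.append((score, start, start + length))
            variant_flags[start] = is_variant
    taken = mask.copy()
    return [
        SegmentHit(table.segment_type, start, end, score,
                   sequence[start:end], k_variant=variant_flags[start])
        for score, start, end in _select_greedy(candidates, taken)
    ]


def _extend_s(sequence: str, start: int, limit: int) -> int:
    """Extend an S seed rightward; return the exclusive end position.

    Extension adds one residue at a time and stops when the last two residues
    of the running segment are both non-serine, or at ``limit`` (the C
    terminus or the first masked position).  A terminating pair of acidic
    residues (D/E) is retained — canonical S segments end in Glu-Asp — while
    any other terminating pair is excluded.
    """
    end = start + 5
    while end < limit:
        end += 1
        a, b = sequence[end - 2], sequence[end - 1]
        if a != "S" and b != "S":
            if a in _ACIDIC and b in _ACIDIC:
                return end
            return end - 2
    return end


def scan_s(
    sequence: str,
    s_table: STable,
    threshold: float,
    seed_fraction: float = 0.5,
    mask: np.ndarray | None = None,
) -> list[SegmentHit]:
    """Seed-and-extend scan for variable-length S segments.

    Five-residue windows whose first-5 score reaches ``seed_fraction`` of the
    threshold are extended rightward until two consecutive non-serine
    residues appear or the C terminus is reached; extended candidates are
    kept if their length-adjusted score passes the threshold and they span at
    least 7 residues.
    """
    n = len(sequence)
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    seed_min = seed_fraction * threshold
    seen: set[tuple[int, int]] = set()
    candidates: list[tuple[float, int, int]] = []
    for seed_start in range(n - 5 + 1):
        if mask[seed_start:seed_start + 5].any():
            continue
        if score_s_first5(sequence, seed_start, s_table) < seed_min:
            continue
        # an S segment is a serine tract: anchor the seed at its first S
        offset = sequence.find("S", seed_start, seed_start + 5)
        if offset < 0:
            continue
        start = offset
        if start + 5 > n or mask[start:start + 5].any():
            continue
        masked_after = np.flatnonzero(mask[start:])
        limit = start + int(masked_after[0]) if masked_after.size else n
        end = _extend_s(sequence, start, limit)
        if end - start < 7 or (start, end) in seen:
            continue
        seen.add((start, end))
        score = score_s_segment(sequence, start, end, s_table)
        if score >= threshold:
            candidates.append((score, start, end))
    taken = mask.copy()
    return [
        SegmentHit("S", start, end, score, sequence[start:end])
        for score, start, end in _select_greedy(candidates, taken)
    ]


def scan_sequence(
    record_or_sequence,
    tables: Mapping[str, FrequencyTable | STable] | None = None,
    config: RunConfig | None = None,
) -> Architecture:
    """Scan one sequence for H, Y, F, S and K segments, in that order.

    Accepts either a :class:`~dhnscan.io.SequenceRecord` or a plain residue
    string.  Earlier-scanned types mask their positions against later types.
    """
    sequence = getattr(record_or_sequence, "sequence", record_or_sequence)
    if not sequence:
        raise ValueError("cannot scan an empty sequence")
    config = config or RunConfig()
    tables = tables or default_tables(pseudocount=config.pseudocount)
    mask = np.zeros(len(sequence), dtype=bool)
    hits: list[SegmentHit] = []

    def claim(new_hits: list[SegmentHit]) -> None:
        for hit in new_hits:
            mask[hit.start:hit.end] = True
        hits.extend(new_hits)

    for seg in ("H", "Y", "F"):
        claim(scan_fixed(sequence, tables[seg], config.threshold(seg), mask))
    claim(
        scan_s(sequence, tables["S"], config.s_threshold,
               config.s_seed_fraction, mask)
    )
    claim(
        scan_fixed(sequence, tables["K"], config.k_threshold, mask,
                   variant_table=tables["Kvariant"])
    )
    hits.sort(key=lambda h: h.start)
    return Architecture(sequence=sequence, hits=hits)
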