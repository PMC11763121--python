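"""Internal repeat detection: seeded families, extension, segment annotation.

Internal duplication is a major mode of dehydrin diversification.  Repeats
are found by enumerating every 6- or 10-residue window, linking windows whose
Hamming identity reaches 80% (>=5/6 or >=8/10 matches) into single-linkage
clusters, reducing each cluster to a maximal left-to-right set of
non-overlapping copies, and keeping families with at least three copies.

Copies can optionally be extended to maximal similar blocks (the published
analysis did this manually, finding repeats of up to ~85 residues), and
annotated with the conserved segments they contain, including low-scoring
segments inferred by position when most sister copies carry one.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from itertools import combinations, groupby
from typing import Iterable, Sequence

import numpy as np

from .scanner import Architecture, SegmentHit, formula_of
from .scoring import SEGMENT_LENGTHS


@dataclass
class RepeatFamily:
    """A set of >=3 mutually similar, non-overlapping substrings."""

    seed_length: int
    copies: list[tuple[int, int]]
    copy_seqs: list[str]
    consensus: str
    #: minimum identity of any copy to the family consensus
    min_pairwise_identity: float
    extended: bool = False

    @property
    def copy_count(self) -> int:
        return len(self.copies)


def hamming_matches(a: str, b: str) -> int:
    return sum(x == y for x, y in zip(a, b))


def identity(a: str, b: str) -> float:
    return hamming_matches(a, b) / len(a)


def _consensus(seqs: Sequence[str]) -> str:
    """Position-wise majority; ties broken alphabetically (deterministic)."""
    out = []
    for column in zip(*seqs):
        counts = Counter(column)
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        out.append(best[0])
    return "".join(out)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def find_repeats(
    sequence: str,
    seed_length: int,
    min_identity: float = 0.8,
    min_copies: int = 3,
) -> list[RepeatFamily]:
    """Find repeat families of ``seed_length``-residue copies.

    All windows are enumerated; windows at Hamming identity >= min_identity
    (integer match floor: ceil(min_identity * seed_length)) are linked into
    single-linkage clusters; overlapping windows within a cluster are reduced
    left-to-right to a maximal non-overlapping set; families with fewer than
    ``min_copies`` copies are discarded.  Families are ordered by the
    position of their first copy.
    """
    n = len(sequence)
    if n < seed_length * min_copies:
        return []
    min_matches = math.ceil(min_identity * seed_length)
    n_windows = n - seed_length + 1
    # vectorized all-pairs Hamming over the window matrix
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, seed_length)
    uf = _UnionFind(n_windows)
    for i in range(n_windows):
        matches = (windows[i + 1:] == windows[i]).sum(axis=1)
        for off in np.flatnonzero(matches >= min_matches):
            uf.union(i, i + 1 + int(off))
    clusters: dict[int, list[int]] = {}
    for i in range(n_windows):
        clusters.setdefault(uf.find(i), []).append(i)

    families = []
    for starts in clusters.values():
        if len(starts) < min_copies:
            continue
        # maximal non-overlapping subset, left to right
        chosen: list[int] = []
        prev_end = -1
        for s in sorted(starts):
            if s >= prev_end:
                chosen.append(s)
                prev_end = s + seed_length
        if len(chosen) < min_copies:
            continue
        seqs = [sequence[s:s + seed_length] for s in chosen]
        cons = _consensus(seqs)
        # enforce the per-copy identity floor against the family consensus
        kept = [
            (s, q) for s, q in zip(chosen, seqs)
            if hamming_matches(q, cons) >= min_matches
        ]
        if len(kept) < min_copies:
            continue
        seqs = [q for _, q in kept]
        cons = _consensus(seqs)
        idents = [identity(q, cons) for q in seqs]
        families.append(
            RepeatFamily(
                seed_length=seed_length,
                copies=[(s, s + seed_length) for s, _ in kept],
                copy_seqs=seqs,
                consensus=cons,
                min_pairwise_identity=min(idents),
            )
        )
    # A repeat region seeds one cluster per alignment frame (windows shifted
    # by one link through their shared core).  Keep the best frame — highest
    # copy count, then identity, then leftmost — and drop families whose
    # copies overlap an already-kept family.
    families.sort(
        key=lambda f: (
            -f.copy_count,
            -round(f.min_pairwise_identity, 9),
            f.copies[0][0],
        )
    )
    kept_families: list[RepeatFamily] = []
    for fam in families:
        clash = any(
            s < e2 and s2 < e
            for s, e in fam.copies
            for kf in kept_families
            for s2, e2 in kf.copies
        )
        if not clash:
            kept_families.append(fam)
    kept_families.sort(key=lambda f: f.copies[0][0])
    return kept_families


def find_all_repeats(
    sequence: str,
    seed_lengths: Sequence[int] = (6, 10),
    min_identity: float = 0.8,
    min_copies: int = 3,
    verbose: bool = False,
) -> list[RepeatFamily]:
    """Run all seed lengths; suppress 6-mer families fully inside 10-mer ones.

    A shorter-seed family whose copies all lie within the copy spans of a
    longer-seed family duplicates that family's evidence and is dropped
    unless ``verbose`` is set.
    """
    all_families: list[RepeatFamily] = []
    for length in sorted(seed_lengths, reverse=True):
        all_families.extend(
            find_repeats(sequence, length, min_identity, min_copies)
        )
    if not verbose:
        longer_spans = [
            fam.copies for fam in all_families
            if fam.seed_length == max(seed_lengths, default=0)
        ]
        covered = [
            iv for copies in longer_spans for iv in copies
        ]

        def inside(fam: RepeatFamily) -> bool:
            return all(
                any(a <= s and e <= b for a, b in covered)
                for s, e in fam.copies
            )

        all_families = [
            fam for fam in all_families
            if fam.seed_length == max(seed_lengths, default=0)
            or not inside(fam)
        ]
    all_families.sort(key=lambda f: (f.copies[0][0], -f.seed_length))
    return all_families


def _mean_pairwise_identity(seqs: Sequence[str]) -> float:
    pairs = list(combinations(seqs, 2))
    if not pairs:
        return 1.0
    return float(np.mean([identity(a, b) for a, b in pairs]))


def extend_family(
    sequence: str, family: RepeatFamily, min_identity: float = 0.8
) -> RepeatFamily:
    """Grow all copies one residue at a time on each side to a maximal block.

    A growth step on a side is accepted while every copy stays in bounds, no
    two copies collide, and the mean pairwise identity over the grown span
    stays >= ``min_identity``.
    """
    copies = sorted(family.copies)

    def valid(cands: list[tuple[int, int]]) -> bool:
        if cands[0][0] < 0 or cands[-1][1] > len(sequence):
            return False
        if any(a[1] > b[0] for a, b in zip(cands, cands[1:])):
            return False
        seqs = [sequence[s:e] for s, e in cands]
        return _mean_pairwise_identity(seqs) >= min_identity

    grew = True
    while grew:
        grew = False
        left = [(s - 1, e) for s, e in copies]
        if valid(left):
            copies, grew = left, True
        right = [(s, e + 1) for s, e in copies]
        if valid(right):
            copies, grew = right, True
    seqs = [sequence[s:e] for s, e in copies]
    cons = _consensus(seqs)
    return replace(
        family,
        copies=copies,
        copy_seqs=seqs,
        consensus=cons,
        min_pairwise_identity=min(identity(q, cons) for q in seqs),
        extended=True,
    )


@dataclass
class CopyAnnotation:
    """Conserved-segment content of one repeat copy."""

    copy: tuple[int, int]
    hits: list[SegmentHit]
    formula: str
    #: (segment_type, absolute_start) sites where most sister copies carry a
    #: segment but this copy has none — inferred low-scoring segments
    inferred_sites: list[tuple[str, int]] = field(default_factory=list)


def annotate_repeat_segments(
    family: RepeatFamily,
    architecture: Architecture,
    offset_tolerance: int = 3,
) -> list[CopyAnnotation]:
    """List the conserved segments overlapping each copy of a family.

    Positions (relative offsets within the copy) where at least half of the
    copies carry a segment of some type are consensus segment sites; copies
    lacking that type near that offset are flagged with an inferred
    low-scoring segment at the corresponding absolute position.
    """
    per_copy_hits = []
    for start, end in family.copies:
        per_copy_hits.append([
            h for h in architecture.hits
            if h.start < end and start < h.end
        ])

    # cluster (type, offset) sites across copies
    site_votes: list[tuple[str, int]] = []
    for (start, _), hits in zip(family.copies, per_copy_hits):
        for h in hits:
            site_votes.append((h.segment_type, h.start - start))
    site_reps: list[tuple[str, int, int]] = []  # (type, offset, votes)
    for seg_type, offset in sorted(site_votes):
        for i, (t, rep, votes) in enumerate(site_reps):
            if t == seg_type and abs(offset - rep) <= offset_tolerance:
                site_reps[i] = (t, rep, votes + 1)
                break
        else:
            site_reps.append((seg_type, offset, 1))
    majority = math.ceil(len(family.copies) / 2)
    consensus_sites = [
        (t, rep) for t, rep, votes in site_reps if votes >= majority
    ]

    annotations = []
    for (start, end), hits in zip(family.copies, per_copy_hits):
        inferred = []
        for seg_type, rep in consensus_sites:
            nearby = [
                h for h in hits
                if h.segment_type == seg_type
                and abs((h.start - start) - rep) <= offset_tolerance
            ]
            if not nearby:
                inferred.append((seg_type, start + rep))
        annotations.append(
            CopyAnnotation(
                copy=(start, end),
                hits=sorted(hits, key=lambda h: h.start),
                formula=formula_of(sorted(hits, key=lambda h: h.start)),
                inferred_sites=sorted(inferred, key=lambda s: s[1]),
            )
        )
    return annotations


def hits_with_inferred(
    architecture: Architecture,
    families: Iterable[RepeatFamily],
    offset_tolerance: int = 3,
) -> list[SegmentHit]:
    """Scanner hits plus low-scoring segments inferred by repeat position."""
    hits = list(architecture.hits)
    occupied = [(h.start, h.end) for h in hits]
    for family in families:
        for ann in annotate_repeat_segments(family, architecture,
                                            offset_tolerance):
            for seg_type, start in ann.inferred_sites:
                length = SEGMENT_LENGTHS.get(seg_type, 7)
                end = min(start + length, len(architecture.sequence))
                if any(start < e and s < end for s, e in occupied):
                    continue
                hits.append(
                    SegmentHit(
                        seg_type, start, end, float("nan"),
                        architecture.sequence[start:end], inferred=True,
                    )
                )
                occupied.append((start, end))
    return sorted(hits, key=lambda h: h.start)


def compound_formula(
    hits: Sequence[SegmentHit], copy_intervals: Sequence[tuple[int, int]]
) -> str:
    """Render a repeat-grouped structural formula, e.g. ``(Y3K)_8Y4(Y3)_2``.

    ``copy_intervals`` are parsed repeat copies (non-overlapping, in
    sequence order).  Hits inside each copy form a block; consecutive
    identical blocks collapse to ``(block)_n``; hits outside any copy are
    rendered with the plain formula grammar.
    """
    copy_intervals = sorted(copy_intervals)
    hits = sorted(hits, key=lambda h: h.start)

    def block_of(hit: SegmentHit) -> int:
        for i, (s, e) in enumerate(copy_intervals):
            if s <= hit.start and hit.end <= e:
                return i
        return -1

    pieces: list[tuple[int, list[SegmentHit]]] = []  # (copy index or -1, hits)
    for hit in hits:
        b = block_of(hit)
        if pieces and pieces[-1][0] == b:
            pieces[-1][1].append(hit)
        else:
            pieces.append((b, [hit]))

    rendered: list[str] = []
    for is_copy, run in groupby(pieces, key=lambda p: p[0] != -1):
        run = list(run)
        if not is_copy:
            for _, seg_hits in run:
                rendered.append(formula_of(seg_hits))
            continue
        blocks = [formula_of(seg_hits) for _, seg_hits in run]
        for block, rep in groupby(blocks):
            count = len(list(rep))
            rendered.append(f"({block})_{count}" if count > 1 else block)
    return "".join(rendered)
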