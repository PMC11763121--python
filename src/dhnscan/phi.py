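"""Descriptive statistics on dehydrin composition and phi linkers.

Covers amino-acid composition and molecular weight, Y-Y spacing (multiple Y
segments are typically separated by only one or two residues), His tallies
in the 6-residue flanks of K segments (reversible His protonation modulates
membrane binding), positional frequency profiles of Y-Y / S-K / K-S phi
linkages, and the distance of the last K segment from the C terminus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight as _bio_mw

from .scanner import Architecture, SegmentHit
from .scoring import AA20

#: C-terminal distance classes for the last K segment (residues after it)
CTERM_CLASSES = ("2-8", "9-16", "17-32", ">32")


@dataclass
class CompositionVector:
    """Amino-acid fractions, length and average molecular weight (kDa)."""

    fractions: pd.Series  # indexed by the 20 standard residues, sums to 1
    length: int
    molecular_weight: float  # kDa, average masses, X excluded
    n_unknown: int = 0  # X residues excluded from MW and fractions


def composition(sequence: str) -> CompositionVector:
    """Composition fractions and average molecular weight of one sequence.

    Fractions are counts over the 20 standard residues divided by their
    total; X residues are excluded from both the fractions and the mass (the
    count of exclusions is reported).  MW uses standard average residue
    masses plus one water, in kDa.
    """
    if not sequence:
        raise ValueError("cannot compute composition of an empty sequence")
    counts = Counter(sequence)
    n_unknown = counts.pop("X", 0)
    bad = set(counts) - set(AA20)
    if bad:
        raise ValueError(f"non-standard residues in sequence: {sorted(bad)}")
    n_std = sum(counts.values())
    if n_std == 0:
        raise ValueError("sequence contains no standard residues")
    fractions = pd.Series(
        {aa: counts.get(aa, 0) / n_std for aa in AA20}, name="fraction"
    )
    stripped = "".join(c for c in sequence if c != "X")
    mw_kda = _bio_mw(stripped, seq_type="protein") / 1000.0
    return CompositionVector(fractions, len(sequence), mw_kda, n_unknown)


def composition_table(
    items: Iterable[tuple[str, str]]
) -> pd.DataFrame:
    """Per-sequence composition rows from (accession, sequence) pairs."""
    rows = []
    for accession, sequence in items:
        vec = composition(sequence)
        row = {"accession": accession, "length": vec.length,
               "mw_kda": vec.molecular_weight, "n_unknown": vec.n_unknown}
        row.update(vec.fractions.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def yy_spacing(
    items: Iterable[tuple[str, Architecture]]
) -> pd.DataFrame:
    """Gap length and sequence between consecutive Y segments, per group.

    ``items`` are (group, architecture) pairs; architectures with fewer than
    two Y segments contribute nothing.
    """
    rows = []
    for group, arch in items:
        y_hits = arch.hits_of("Y")
        for left, right in zip(y_hits, y_hits[1:]):
            between = [
                h for h in arch.hits if left.end <= h.start < right.start
            ]
            if between:  # not a direct Y-Y linkage
                continue
            rows.append({
                "group": group,
                "gap_length": right.start - left.end,
                "gap_sequence": arch.sequence[left.end:right.start],
            })
    return pd.DataFrame(rows, columns=["group", "gap_length", "gap_sequence"])


def his_flank_tally(
    sequence: str, k_hits: Sequence[SegmentHit]
) -> pd.DataFrame:
    """His counts in the up-to-6-residue prefix and suffix of each K segment.

    Windows truncate at the sequence bounds, so a K segment ending within 6
    residues of the C terminus is tallied over as few residues as remain.
    """
    rows = []
    for hit in k_hits:
        p_start = max(0, hit.start - 6)
        s_end = min(len(sequence), hit.end + 6)
        prefix = sequence[p_start:hit.start]
        suffix = sequence[hit.end:s_end]
        rows.append({
            "start": hit.start, "end": hit.end,
            "prefix_len": len(prefix), "suffix_len": len(suffix),
            "prefix_h": prefix.count("H"), "suffix_h": suffix.count("H"),
        })
    return pd.DataFrame(
        rows,
        columns=["start", "end", "prefix_len", "suffix_len",
                 "prefix_h", "suffix_h"],
    )


def his_flank_summary(tally: pd.DataFrame) -> dict[str, float]:
    """Fractions of K segments with >=1 and >=2 flanking His residues."""
    if tally.empty:
        return {"ge1": 0.0, "ge2": 0.0, "n": 0}
    total = tally["prefix_h"] + tally["suffix_h"]
    return {
        "ge1": float((total >= 1).mean()),
        "ge2": float((total >= 2).mean()),
        "n": int(len(tally)),
    }


@dataclass
class LinkageProfile:
    """Aligned per-position residue frequencies for one phi-linkage context."""

    context: str  # "Y-Y", "S-K" or "K-S"
    freqs: pd.DataFrame  # up to 10 rows (positions) x 20 residues
    length_counts: Counter
    n: int
    degenerate: bool = False  # fewer than 2 linkages observed


_CONTEXT_PAIRS = {"Y-Y": ("Y", "Y"), "S-K": ("S", "K"), "K-S": ("K", "S")}


def linkage_profile(
    items: Iterable[tuple[str, Architecture]],
    context: str,
    max_positions: int = 10,
) -> LinkageProfile:
    """Profile phi linkers of one context, aligned at their first residue.

    Linkers are collected between directly consecutive hits of the context
    pair and aligned at the residue immediately after the N-terminal
    enclosing segment; per-position frequencies are reported for up to
    ``max_positions`` positions together with the length histogram.
    """
    if context not in _CONTEXT_PAIRS:
        raise ValueError(f"unknown linkage context {context!r}")
    left_t, right_t = _CONTEXT_PAIRS[context]
    linkers: list[str] = []
    for _, arch in items:
        for a, b in zip(arch.hits, arch.hits[1:]):
            if a.segment_type == left_t and b.segment_type == right_t:
                linkers.append(arch.sequence[a.end:b.start])
    counts = np.zeros((max_positions, len(AA20)))
    lengths = Counter(len(s) for s in linkers)
    for s in linkers:
        for p, residue in enumerate(s[:max_positions]):
            if residue in AA20:
                counts[p, AA20.index(residue)] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    return LinkageProfile(
        context=context,
        freqs=pd.DataFrame(
            freqs, index=range(1, max_positions + 1), columns=list(AA20)
        ),
        length_counts=lengths,
        n=len(linkers),
        degenerate=len(linkers) < 2,
    )


def parse_ks_linkage(
    linker: str, min_run: int = 3, k_fraction: float = 2 / 3
) -> tuple[str, str, str] | None:
    """Split a K-S linker into its three domains around the poly-K run.

    The poly-K run is the longest stretch that starts and ends with K, has at
    least ``min_run`` residues and at least ``k_fraction`` K content; what
    precedes it is the first Gly/Asp/Glu(/His) mix and what follows is the
    second.  Returns None when no qualifying run exists.
    """
    best: tuple[int, int] | None = None
    n = len(linker)
    for i in range(n):
        if linker[i] != "K":
            continue
        k_count = 0
        for j in range(i, n):
            if linker[j] == "K":
                k_count += 1
                span = j - i + 1
                if span >= min_run and k_count / span >= k_fraction:
                    if best is None or span > best[1] - best[0]:
                        best = (i, j + 1)
    if best is None:
        return None
    i, j = best
    return linker[:i], linker[i:j], linker[j:]


def cterm_distance_classes(
    items: Iterable[tuple[str, Architecture]]
) -> pd.DataFrame:
    """Distance classes of the last K segment from the C terminus, per group.

    Only architectures lacking a terminal S segment count (for the others
    the chain ends in S, not K); distance is the number of residues after
    the last K hit, binned into the 2-8 / 9-16 / 17-32 / >32 classes.
    """
    rows = []
    for group, arch in items:
        k_hits = arch.hits_of("K")
        if not k_hits:
            continue
        last_hit = arch.hits[-1]
        if last_hit.segment_type == "S":  # terminal-S architectures excluded
            continue
        distance = len(arch.sequence) - k_hits[-1].end
        if distance <= 8:
            cls = "2-8"
        elif distance <= 16:
            cls = "9-16"
        elif distance <= 32:
            cls = "17-32"
        else:
            cls = ">32"
        rows.append({"group": group, "distance": distance, "class": cls})
    return pd.DataFrame(rows, columns=["group", "distance", "class"])
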