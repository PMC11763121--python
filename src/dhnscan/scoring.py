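"""Position-frequency tables and window scoring for conserved dehydrin segments.

Dehydrins are recognized by five short conserved motifs (K, Y, F, H and the
variable-length serine-rich S segment) embedded in disordered, glycine/polar
rich linkers.  Each fixed-length motif is modelled by a per-position relative
frequency table built from a library of previously identified segments; a
candidate window is scored by summing the table frequency of its residue at
every position, so scores range from 0 to the motif length and a perfectly
consensus-matching window in a single-sequence, pseudocount-free table scores
exactly the motif length.

The S segment is variable in length and is scored against a three-block table
(first five residues, pooled interior, last two residues); the interior block
contributes three times its mean per-position frequency, giving every S
segment a fixed score range of [0, 10] regardless of length.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

#: The 20 standard amino acids in alphabetical one-letter order, plus X for
#: unknown residues.  X never takes part in normalization; it always scores
#: the pseudocount floor.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "X"
AA_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(ALPHABET)}

#: Fixed motif lengths.  K, its HKn(S)-order variant, and H are 15-mers, Y is
#: an 8-mer and F a 10-mer; S is variable and handled by :class:`STable`.
SEGMENT_LENGTHS = {"K": 15, "Kvariant": 15, "H": 15, "Y": 8, "F": 10}

DEFAULT_PSEUDOCOUNT = 0.01

_WATER = 18.0153


class LibraryError(ValueError):
    """A segment library is empty or contains entries of the wrong length."""


def _validate_library(library: Sequence[str], length: int | None) -> list[str]:
    entries = [str(s).upper() for s in library]
    if not entries:
        raise LibraryError("segment library is empty")
    bad = [s for s in entries if any(c not in AA20 for c in s)]
    if bad:
        raise LibraryError(f"library entries with non-standard residues: {bad}")
    if length is not None:
        wrong = [s for s in entries if len(s) != length]
        if wrong:
            raise LibraryError(
                f"library entries with length != {length}: {wrong}"
            )
    return entries


@dataclass(frozen=True)
class FrequencyTable:
    """Per-position residue frequencies for one fixed-length segment type.

    ``freqs`` is a ``(length, 21)`` matrix over :data:`ALPHABET`; each row
    sums to 1 over the 20 standard residues (the X column carries the
    pseudocount floor and is excluded from normalization).
    """

    segment_type: str
    freqs: np.ndarray
    pseudocount: float
    library_size: int

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def score(self, sequence: str, start: int) -> float:
        return score_window(sequence, start, self)


@dataclass(frozen=True)
class STable:
    """Three-block frequency table for the variable-length S segment."""

    first5: np.ndarray   # (5, 21)
    interior: np.ndarray  # (21,), pooled over all interior positions
    last2: np.ndarray    # (2, 21)
    pseudocount: float
    library_size: int


def build_table(
    library: Sequence[str],
    segment_type: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> FrequencyTable:
    """Build a per-position frequency table from a segment library.

    freqs[p][a] = (count of residue a at position p + pseudocount)
                  / (library size + 20 * pseudocount)
    """
    if segment_type not in SEGMENT_LENGTHS:
        raise ValueError(f"unknown fixed-length segment type {segment_type!r}")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    length = SEGMENT_LENGTHS[segment_type]
    entries = _validate_library(library, length)
    n = len(entries)
    counts = np.zeros((length, 21))
    for entry in entries:
        for p, residue in enumerate(entry):
            counts[p, AA_INDEX[residue]] += 1
    denom = n + 20.0 * pseudocount
    freqs = (counts + pseudocount) / denom
    freqs[:, AA_INDEX["X"]] = pseudocount / denom
    return FrequencyTable(segment_type, freqs, pseudocount, n)


def build_s_table(
    library: Sequence[str], pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> STable:
    """Build the three-block S table (first 5 / pooled interior / last 2)."""
    entries = _validate_library(library, None)
    short = [s for s in entries if len(s) < 7]
    if short:
        raise LibraryError(f"S library entries shorter than 7 residues: {short}")
    n = len(entries)
    denom = n + 20.0 * pseudocount
    first5 = np.zeros((5, 21))
    last2 = np.zeros((2, 21))
    interior = np.zeros(21)
    n_interior = 0
    for entry in entries:
        for p in range(5):
            first5[p, AA_INDEX[entry[p]]] += 1
        last2[0, AA_INDEX[entry[-2]]] += 1
        last2[1, AA_INDEX[entry[-1]]] += 1
        for residue in entry[5:-2]:
            interior[AA_INDEX[residue]] += 1
            n_interior += 1
    first5 = (first5 + pseudocount) / denom
    last2 = (last2 + pseudocount) / denom
    idenom = n_interior + 20.0 * pseudocount
    interior = (interior + pseudocount) / idenom
    floor_f = pseudocount / denom
    first5[:, AA_INDEX["X"]] = floor_f
    last2[:, AA_INDEX["X"]] = floor_f
    interior[AA_INDEX["X"]] = pseudocount / idenom
    return STable(first5, interior, last2, pseudocount, n)


def apply_gc_variant(table: FrequencyTable) -> FrequencyTable:
    """Adjust an F table so GC-variant segments (GCGMFDFLKK-like) score well.

    The frequency of G at position 1 is set to that of D, and of C at
    position 2 to that of R, leaving all other cells unchanged.  Idempotent.
    """
    if table.segment_type != "F":
        raise ValueError("GC-variant adjustment applies only to F tables")
    freqs = table.freqs.copy()
    freqs[0, AA_INDEX["G"]] = freqs[0, AA_INDEX["D"]]
    freqs[1, AA_INDEX["C"]] = freqs[1, AA_INDEX["R"]]
    return replace(table, freqs=freqs)


def score_window(sequence: str, start: int, table: FrequencyTable) -> float:
    """Sum of per-position table frequencies over one fixed-length window."""
    length = table.length
    if start < 0 or start + length > len(sequence):
        raise IndexError(
            f"window [{start}, {start + length}) out of bounds for sequence "
            f"of length {len(sequence)}"
        )
    total = 0.0
    freqs = table.freqs
    for p in range(length):
        residue = sequence[start + p]
        try:
            total += freqs[p, AA_INDEX[residue]]
        except KeyError:
            raise ValueError(
                f"residue {residue!r} at position {start + p} is not in the "
                "accepted alphabet"
            ) from None
    return float(total)


def score_s_first5(sequence: str, start: int, s_table: STable) -> float:
    """Score only the first five residues of a candidate S seed window."""
    if start < 0 or start + 5 > len(sequence):
        raise IndexError("S seed window out of bounds")
    return float(
        sum(s_table.first5[p, AA_INDEX[sequence[start + p]]] for p in range(5))
    )


def score_s_segment(sequence: str, start: int, end: int, s_table: STable) -> float:
    """Length-adjusted S-segment score with fixed range [0, 10].

    score = sum of first-5 lookups
            + 3 * mean interior lookup over positions 6..end-2
            + sum of last-2 lookups
    A 7-residue segment has no interior positions and the interior term is 0.
    """
    length = end - start
    if length < 7:
        raise ValueError(f"S segment [{start}, {end}) shorter than 7 residues")
    if start < 0 or end > len(sequence):
        raise IndexError("S segment out of bounds")
    seg = sequence[start:end]
    total = sum(s_table.first5[p, AA_INDEX[seg[p]]] for p in range(5))
    inner = seg[5:-2]
    if inner:
        total += 3.0 * float(
            np.mean([s_table.interior[AA_INDEX[c]] for c in inner])
        )
    total += s_table.last2[0, AA_INDEX[seg[-2]]]
    total += s_table.last2[1, AA_INDEX[seg[-1]]]
    return float(total)


# ---------------------------------------------------------------------------
# Bundled default tables
# ---------------------------------------------------------------------------

_LIBRARY_FILES = {
    "K": "k_segments.txt",
    "Kvariant": "kvariant_segments.txt",
    "Y": "y_segments.txt",
    "F": "f_segments.txt",
    "H": "h_segments.txt",
    "S": "s_segments.txt",
}


def bundled_library(segment_type: str) -> list[str]:
    """Return the bundled consensus-derived library for one segment type."""
    if segment_type not in _LIBRARY_FILES:
        raise ValueError(f"no bundled library for segment type {segment_type!r}")
    text = (
        importlib.resources.files("dhnscan.data")
        .joinpath(_LIBRARY_FILES[segment_type])
        .read_text()
    )
    return [line.strip() for line in text.splitlines() if line.strip()]


def default_tables(
    pseudocount: float = DEFAULT_PSEUDOCOUNT, gc_variant: bool = True
) -> dict[str, FrequencyTable | STable]:
    """Build the default scoring tables from the bundled consensus libraries.

    The F table has the GC-variant adjustment applied by default so that both
    canonical and GC-variant F segments are detected in a single pass.
    """
    tables: dict[str, FrequencyTable | STable] = {}
    for seg in ("K", "Kvariant", "Y", "F", "H"):
        tables[seg] = build_table(bundled_library(seg), seg, pseudocount)
    if gc_variant:
        tables["F"] = apply_gc_variant(tables["F"])
    tables["S"] = build_s_table(bundled_library("S"), pseudocount)
    return tables


# ---------------------------------------------------------------------------
# TSV serialization (rows = positions, columns = residues)
# ---------------------------------------------------------------------------

def write_table(table: FrequencyTable | STable, path: str | Path) -> None:
    path = Path(path)
    lines = []
    if isinstance(table, FrequencyTable):
        lines.append(
            f"#segment_type={table.segment_type}\tpseudocount={table.pseudocount}"
            f"\tlibrary_size={table.library_size}"
        )
        lines.append("pos\t" + "\t".join(ALPHABET))
        for p in range(table.length):
            row = "\t".join(repr(float(v)) for v in table.freqs[p])
            lines.append(f"{p + 1}\t{row}")
    else:
        lines.append(
            f"#segment_type=S\tpseudocount={table.pseudocount}"
            f"\tlibrary_size={table.library_size}"
        )
        lines.append("pos\t" + "\t".join(ALPHABET))
        blocks = [(f"first5_{p + 1}", table.first5[p]) for p in range(5)]
        blocks.append(("interior", table.interior))
        blocks += [(f"last2_{p + 1}", table.last2[p]) for p in range(2)]
        for name, vec in blocks:
            row = "\t".join(repr(float(v)) for v in vec)
            lines.append(f"{name}\t{row}")
    path.write_text("\n".join(lines) + "\n")


def read_table(path: str | Path) -> FrequencyTable | STable:
    lines = Path(path).read_text().splitlines()
    meta = dict(
        field.split("=", 1) for field in lines[0].lstrip("#").split("\t")
    )
    segment_type = meta["segment_type"]
    pseudocount = float(meta["pseudocount"])
    library_size = int(meta["library_size"])
    header = lines[1].split("\t")[1:]
    if header != list(ALPHABET):
        raise ValueError(f"unexpected residue columns in {path}")
    rows = {}
    for line in lines[2:]:
        fields = line.split("\t")
        rows[fields[0]] = np.array([float(v) for v in fields[1:]])
    if segment_type == "S":
        first5 = np.vstack([rows[f"first5_{p + 1}"] for p in range(5)])
        last2 = np.vstack([rows[f"last2_{p + 1}"] for p in range(2)])
        return STable(first5, rows["interior"], last2, pseudocount, library_size)
    freqs = np.vstack([rows[str(p + 1)] for p in range(len(rows))])
    return FrequencyTable(segment_type, freqs, pseudocount, library_size)
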