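"""Reading and writing the external formats: FASTA, segment libraries,
annotation tables and the four per-run output tables.

Output tables are tab-separated with a single header row and 1-based
inclusive coordinates (the convention biologists expect); all internal
computation is 0-based half-open, and the conversion happens only here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .scoring import ALPHABET, SEGMENT_LENGTHS

MAJOR_GROUPS = (
    "Chlorophyta", "Bryophyte", "Pteridophyte", "Gymnosperm",
    "Basal angiosperm", "Magnoliid", "Monocot", "Basal eudicot",
    "Carophyllid", "Rosid", "Asterid",
)

_PARTIAL_RE = re.compile(r"\bpartial\b", re.IGNORECASE)


class FastaParseError(ValueError):
    """Malformed FASTA input (with the offending line or accession named)."""


@dataclass
class SequenceRecord:
    """One protein sequence with its NCBI-style header fields.

    A record is flagged partial when its description contains the token
    "partial" or its first residue is not the initiator methionine.
    """

    accession: str
    description: str
    sequence: str
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        for pos, residue in enumerate(self.sequence):
            if residue not in ALPHABET:
                raise ValueError(
                    f"{self.accession}: residue {residue!r} at position "
                    f"{pos + 1} is outside the accepted alphabet"
                )
        self.partial = bool(
            _PARTIAL_RE.search(self.description) or self.sequence[0] != "M"
        )

    def __len__(self) -> int:
        return len(self.sequence)


def make_record(header: str, raw_sequence: str) -> SequenceRecord:
    """Build a record from an NCBI-style header and raw sequence text.

    The accession is the first whitespace-delimited header token; the rest is
    the description.  The sequence is uppercased and '*' stop characters are
    stripped.
    """
    parts = header.split(None, 1)
    accession = parts[0] if parts else ""
    description = parts[1] if len(parts) > 1 else ""
    sequence = raw_sequence.upper().replace("*", "").replace(" ", "")
    return SequenceRecord(accession, description, sequence)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records, preserving file order."""
    path = Path(path)
    with open(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
        if not first.startswith(">"):
            raise FastaParseError(
                f"{path}: first non-blank line is not a FASTA header: "
                f"{first.strip()!r}"
            )
        handle.seek(0)
        records = []
        for header, seq in SimpleFastaParser(handle):
            if not seq:
                raise FastaParseError(
                    f"{path}: record {header.split()[0]!r} has an empty "
                    "sequence"
                )
            records.append(make_record(header, seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    lines = []
    for rec in records:
        header = f">{rec.accession}"
        if rec.description:
            header += f" {rec.description}"
        lines.append(header)
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i:i + width])
    Path(path).write_text("\n".join(lines) + "\n")


def read_segment_library(path: str | Path, segment_type: str) -> list[str]:
    """Read a segment library (FASTA or one-sequence-per-line text).

    Entries for the fixed-length types (K, Kvariant, H: 15; Y: 8; F: 10)
    must all have exactly the expected length; S entries may vary.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        with open(path) as handle:
            entries = [seq.upper() for _, seq in SimpleFastaParser(handle)]
    else:
        entries = [
            line.strip().upper() for line in text.splitlines() if line.strip()
        ]
    expected = SEGMENT_LENGTHS.get(segment_type)
    if segment_type not in SEGMENT_LENGTHS and segment_type != "S":
        raise ValueError(f"unknown segment type {segment_type!r}")
    if expected is not None:
        wrong = [e for e in entries if len(e) != expected]
        if wrong:
            raise ValueError(
                f"{path}: {segment_type} entries must have length "
                f"{expected}; offending entries: {wrong}"
            )
    return entries


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an accession -> taxonomy annotation table (TSV).

    Expected columns: accession, species, genus, family, major_group; the
    major group, when present, must be one of the recognized lineages.
    """
    table = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"accession", "species", "genus", "family", "major_group"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = set(table["major_group"]) - set(MAJOR_GROUPS) - {""}
    if bad:
        raise ValueError(f"{path}: unknown major groups {sorted(bad)}")
    return table


# ---------------------------------------------------------------------------
# The four per-run output tables
# ---------------------------------------------------------------------------

DHN_TYPES_COLUMNS = [
    "accession", "description", "formula", "group", "order", "length",
    "mw_kda", "max_k_score", "partial",
]
SEGMENTS_COLUMNS = [
    "accession", "segment_type", "start", "end", "score",
    "segment_sequence", "preceding_phi",
]
REPEAT_SUMMARY_COLUMNS = [
    "accession", "family", "seed_length", "copy_count", "consensus",
    "copy_sequences",
]
REPEATS_COLUMNS = [
    "accession", "family", "copy_index", "start", "end", "copy_sequence",
]


def write_output_tables(results: Sequence, out_dir: str | Path) -> dict[str, Path]:
    """Write dhn_types / segments / repeat_summary / repeats TSV tables.

    ``results`` are per-sequence analysis results (see
    :func:`dhnscan.pipeline.analyze_records`); only sequences passing the
    K-segment screen appear in dhn_types.tsv.  Coordinates are 1-based
    inclusive.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    types_rows, segment_rows, summary_rows, repeat_rows = [], [], [], []
    for res in results:
        acc = res.record.accession
        if res.classification is not None:
            types_rows.append({
                "accession": acc,
                "description": res.record.description,
                "formula": res.architecture.formula,
                "group": res.classification.group,
                "order": res.classification.order,
                "length": len(res.record.sequence),
                "mw_kda": round(res.composition.molecular_weight, 4),
                "max_k_score": round(res.classification.max_k_score, 4),
                "partial": res.record.partial,
            })
        for hit in res.architecture.hits:
            segment_rows.append({
                "accession": acc,
                "segment_type": (
                    "Kvariant" if hit.k_variant else hit.segment_type
                ),
                "start": hit.start + 1,
                "end": hit.end,
                "score": round(hit.score, 4),
                "segment_sequence": hit.sequence,
                "preceding_phi": res.architecture.phi_before(hit),
            })
        for phi in res.architecture.phi_segments():
            if phi.kind == "C-terminal":
                segment_rows.append({
                    "accession": acc,
                    "segment_type": "phi-C-terminal",
                    "start": phi.start + 1,
                    "end": phi.end,
                    "score": "",
                    "segment_sequence": phi.sequence,
                    "preceding_phi": "",
                })
        for fam_idx, family in enumerate(res.repeat_families, 1):
            summary_rows.append({
                "accession": acc,
                "family": fam_idx,
                "seed_length": family.seed_length,
                "copy_count": family.copy_count,
                "consensus": family.consensus,
                "copy_sequences": ",".join(family.copy_seqs),
            })
            for copy_idx, ((start, end), seq) in enumerate(
                zip(family.copies, family.copy_seqs), 1
            ):
                repeat_rows.append({
                    "accession": acc,
                    "family": fam_idx,
                    "copy_index": copy_idx,
                    "start": start + 1,
                    "end": end,
                    "copy_sequence": seq,
                })

    paths = {}
    for name, rows, columns in (
        ("dhn_types", types_rows, DHN_TYPES_COLUMNS),
        ("segments", segment_rows, SEGMENTS_COLUMNS),
        ("repeat_summary", summary_rows, REPEAT_SUMMARY_COLUMNS),
        ("repeats", repeat_rows, REPEATS_COLUMNS),
    ):
        path = out_dir / f"{name}.tsv"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths
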