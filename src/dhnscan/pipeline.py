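"""End-to-end analysis: scan -> classify -> repeats -> composition.

This is the glue the CLI and the output tables are built on; each step is a
thin call into the corresponding module so library users can run any subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .classify import Classification, classify
from .config import RunConfig
from .io import SequenceRecord
from .phi import CompositionVector, composition
from .repeats import RepeatFamily, extend_family, find_all_repeats
from .scanner import Architecture, scan_sequence
from .scoring import FrequencyTable, STable, default_tables, read_table


@dataclass
class SequenceResult:
    record: SequenceRecord
    architecture: Architecture
    classification: Classification | None  # None: no K hit, not a candidate
    composition: CompositionVector
    repeat_families: list[RepeatFamily] = field(default_factory=list)


def load_tables(config: RunConfig) -> dict[str, FrequencyTable | STable]:
    """Default consensus tables, or TSV overrides from config.table_dir."""
    tables = default_tables(pseudocount=config.pseudocount)
    if config.table_dir:
        from pathlib import Path

        for path in sorted(Path(config.table_dir).glob("*.tsv")):
            table = read_table(path)
            key = "S" if isinstance(table, STable) else table.segment_type
            tables[key] = table
    return tables


def analyze_record(
    record: SequenceRecord,
    config: RunConfig | None = None,
    tables: Mapping[str, FrequencyTable | STable] | None = None,
) -> SequenceResult:
    config = config or RunConfig()
    tables = tables or load_tables(config)
    arch = scan_sequence(record, tables, config)
    cls = classify(arch, config, partial=record.partial)
    families: list[RepeatFamily] = []
    if arch.hits:  # repeats are searched only in sequences with any segment
        families = find_all_repeats(
            record.sequence,
            seed_lengths=config.repeat_seed_lengths,
            min_identity=config.repeat_min_identity,
            min_copies=config.repeat_min_copies,
        )
        if config.repeat_extend:
            families = [
                extend_family(record.sequence, fam,
                              config.repeat_min_identity)
                for fam in families
            ]
    return SequenceResult(
        record=record,
        architecture=arch,
        classification=cls,
        composition=composition(record.sequence),
        repeat_families=families,
    )


def analyze_records(
    records: Sequence[SequenceRecord],
    config: RunConfig | None = None,
) -> list[SequenceResult]:
    config = config or RunConfig()
    tables = load_tables(config)
    return [analyze_record(rec, config, tables) for rec in records]


def funnel_counts(results: Sequence[SequenceResult]) -> dict[str, int]:
    """Candidate funnel: inputs -> K-passing -> screened out -> confirmed."""
    k_passing = [r for r in results if r.classification is not None]
    screened = [
        r for r in k_passing
        if r.classification.group in ("pseudo", "reticulon")
    ]
    return {
        "candidates": len(results),
        "k_passing": len(k_passing),
        "pseudo_or_reticulon": len(screened),
        "confirmed": len(k_passing) - len(screened),
        "partial": sum(
            1 for r in k_passing if "partial" in r.classification.flags
        ),
    }
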