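"""Synthetic dehydrin-like sequences with exact ground truth.

Sequences are assembled from consensus-derived conserved segments joined by
random glycine/polar-enriched phi linkers, mimicking the architecture of real
dehydrins: an initiator methionine, closely spaced Y segments, S segments
ending in Glu-Asp, C-terminal K segments, and optional planted repeat blocks.

Background phi linkers are sampled by rejection: a draw is discarded if the
assembled sequence, scanned at mutation rate 0, contains any above-threshold
window beyond the planted segments (or misses one).  The emitted ground truth
is therefore the *complete* truth for the sequence, which is what makes
planted-architecture recovery a meaningful property.  Point substitutions, if
requested, are applied after this check, so at non-zero mutation rates the
recovery rate measures genuine robustness, not construction artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import RunConfig
from .io import SequenceRecord
from .scanner import Architecture, formula_of, scan_sequence
from .scoring import ALPHABET, AA20, default_tables

#: canonical realization of each segment type (argmax of the default tables)
CANONICAL_SEGMENTS = {
    "K": "EKKGIMDKIKEKLPG",
    "Kvariant": "HKEGFVDKIKDKIHG",
    "Y": "TDEYGNPV",
    "F": "DRGLFDFLGK",
    "H": "MAGIIHKIEETLHIG",
    "S": "SSSSSSSSSSED",
}

#: default phi composition: Gly 0.20, the nine polar residues share 0.60,
#: the remaining ten residues share 0.20
_POLAR = "STNQEDKRH"


def default_phi_composition() -> dict[str, float]:
    comp = {aa: 0.2 / 10 for aa in AA20 if aa not in _POLAR and aa != "G"}
    comp.update({aa: 0.6 / 9 for aa in _POLAR})
    comp["G"] = 0.2
    return comp


@dataclass
class RepeatPlant:
    """A repeat block to plant: ``copies`` copies of ``unit`` with spacers."""

    unit: str
    copies: int
    spacer_range: tuple[int, int] = (2, 6)


@dataclass
class SyntheticSpec:
    architecture: list[str]
    phi_length_range: tuple[int, int] = (2, 12)
    #: consecutive Y segments are closely spaced in real dehydrins
    yy_gap_range: tuple[int, int] = (1, 2)
    phi_composition: Mapping[str, float] | None = None
    mutation_rate: float = 0.0
    repeat_plant: RepeatPlant | None = None
    #: None = use the variant K consensus iff the architecture contains H
    use_kvariant_k: bool | None = None
    seed: int = 0
    accession: str = "SYN"

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        unknown = set(self.architecture) - {"H", "Y", "F", "S", "K"}
        if unknown:
            raise ValueError(f"unknown segment types {sorted(unknown)}")
        comp = dict(self.phi_composition or default_phi_composition())
        total = sum(comp.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("phi composition probabilities must sum to 1")
        self.phi_composition = comp


@dataclass
class GroundTruth:
    """Planted segment and repeat coordinates (0-based half-open)."""

    segments: list[tuple[str, int, int]]
    repeat_copies: list[tuple[int, int]] = field(default_factory=list)

    @property
    def formula(self) -> str:
        letters = [t for t, _, _ in self.segments]
        out, prev, count = [], None, 0
        for letter in letters + [None]:
            if letter == prev:
                count += 1
                continue
            if prev is not None:
                out.append(prev if count == 1 else f"{prev}{count}")
            prev, count = letter, 1
        return "".join(out)


def _sample_phi(rng: np.random.Generator, length: int,
                comp: Mapping[str, float]) -> str:
    residues = list(comp)
    probs = np.array([comp[r] for r in residues])
    return "".join(rng.choice(residues, size=length, p=probs)) if length else ""


def _assemble(spec: SyntheticSpec, rng: np.random.Generator
              ) -> tuple[str, GroundTruth]:
    comp = spec.phi_composition
    lo, hi = spec.phi_length_range
    use_variant = (
        spec.use_kvariant_k
        if spec.use_kvariant_k is not None
        else "H" in spec.architecture
    )
    parts: list[str] = []
    segments: list[tuple[str, int, int]] = []
    pos = 0

    def push(text: str) -> None:
        nonlocal pos
        parts.append(text)
        pos += len(text)

    if spec.architecture and spec.architecture[0] == "H":
        pass  # the H segment's own Met is the initiator
    else:
        push("M")
        push(_sample_phi(rng, int(rng.integers(lo, hi + 1)), comp))

    prev: str | None = None
    for seg_type in spec.architecture:
        if prev is not None:
            if prev == "Y" and seg_type == "Y":
                glo, ghi = spec.yy_gap_range
            else:
                glo, ghi = lo, hi
            push(_sample_phi(rng, int(rng.integers(glo, ghi + 1)), comp))
        realized = CANONICAL_SEGMENTS[
            "Kvariant" if seg_type == "K" and use_variant else seg_type
        ]
        segments.append((seg_type, pos, pos + len(realized)))
        push(realized)
        prev = seg_type

    repeat_copies: list[tuple[int, int]] = []
    if spec.repeat_plant is not None:
        plant = spec.repeat_plant
        slo, shi = plant.spacer_range
        push(_sample_phi(rng, int(rng.integers(lo, hi + 1)), comp))
        for i in range(plant.copies):
            if i:
                push(_sample_phi(rng, int(rng.integers(slo, shi + 1)), comp))
            repeat_copies.append((pos, pos + len(plant.unit)))
            push(plant.unit)

    if spec.architecture and spec.architecture[-1] == "S":
        tail = int(rng.integers(0, 4))  # keep the S segment terminal
    else:
        tail = int(rng.integers(2, 8))
    push(_sample_phi(rng, tail, comp))
    return "".join(parts), GroundTruth(segments, repeat_copies)


def _matches_truth(arch: Architecture, truth: GroundTruth) -> bool:
    """Scanner output equals the planted segments, ignoring hits inside
    planted repeat blocks (repeat units may legitimately contain segments)."""
    found = {
        (h.segment_type, h.start, h.end)
        for h in arch.hits
        if not any(s <= h.start and h.end <= e
                   for s, e in truth.repeat_copies)
    }
    return found == set(truth.segments)


def generate(
    spec: SyntheticSpec,
    config: RunConfig | None = None,
    max_tries: int = 50,
) -> tuple[SequenceRecord, GroundTruth]:
    """Generate one sequence plus its ground truth; deterministic per seed."""
    config = config or RunConfig()
    tables = default_tables(pseudocount=config.pseudocount)
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_tries):
        sequence, truth = _assemble(spec, rng)
        if _matches_truth(scan_sequence(sequence, tables, config), truth):
            break
    else:
        raise RuntimeError(
            "could not assemble a sequence whose scan matches the planted "
            f"architecture after {max_tries} attempts; the spec may be "
            "contradictory"
        )
    if spec.mutation_rate > 0:
        residues = list(sequence)
        hit_mask = rng.random(len(residues)) < spec.mutation_rate
        for i in np.flatnonzero(hit_mask):
            if i == 0:  # keep the initiator Met
                continue
            options = [a for a in AA20 if a != residues[i]]
            residues[i] = str(rng.choice(options))
        sequence = "".join(residues)
    record = SequenceRecord(spec.accession, "synthetic dehydrin", sequence)
    return record, truth


_GROUP_ORDER = {
    "YnSKn": "Yn(S)Kn", "YnKn": "Yn(S)Kn",
    "FSKn": "F(S)Kn", "FKn": "F(S)Kn",
    "HKnS": "(H)KnS", "HKn": "(H)KnS", "KnS": "(H)KnS",
    "Kn": "unassigned", "K1": "unassigned", "SKn": "unassigned",
}

#: complete-sequence group frequencies, matching the published cohort
DEFAULT_GROUP_MIX = {
    "YnSKn": 0.36, "FSKn": 0.22, "SKn": 0.17, "Kn": 0.14,
    "HKnS": 0.09, "KnS": 0.02,
}


def _architecture_for(group: str, rng: np.random.Generator) -> list[str]:
    k = int(rng.integers(1, 4))
    y = int(rng.integers(1, 4))
    return {
        "YnSKn": ["Y"] * y + ["S"] + ["K"] * k,
        "YnKn": ["Y"] * y + ["K"] * max(k, 1),
        "FSKn": ["F", "S"] + ["K"] * k,
        "FKn": ["F"] + ["K"] * k,
        "SKn": ["S"] + ["K"] * k,
        "Kn": ["K"] * (k + 1),
        "K1": ["K"],
        "KnS": ["K"] * k + ["S"],
        "HKnS": ["H", "K", "S"],
        "HKn": ["H"] + ["K"] * k,
    }[group]


def generate_cohort(
    n: int,
    group_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    mutation_rate: float = 0.02,
    config: RunConfig | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate ``n`` records with canonical per-group architectures.

    Returns the records and a ground-truth table (accession, group, order,
    formula, segment coordinates as a semicolon-joined string).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = dict(group_mix or DEFAULT_GROUP_MIX)
    groups = list(mix)
    probs = np.array([mix[g] for g in groups], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    records, rows = [], []
    for i in range(n):
        group = str(rng.choice(groups, p=probs))
        arch_letters = _architecture_for(group, rng)
        spec = SyntheticSpec(
            architecture=arch_letters,
            mutation_rate=mutation_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            accession=f"SYN{i + 1:06d}",
        )
        record, truth = generate(spec, config)
        records.append(record)
        rows.append({
            "accession": record.accession,
            "group": group,
            "order": _GROUP_ORDER[group],
            "formula": truth.formula,
            "segments": ";".join(
                f"{t}:{s}-{e}" for t, s, e in truth.segments
            ),
        })
    return records, pd.DataFrame(rows)
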