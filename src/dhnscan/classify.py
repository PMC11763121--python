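"""Group and order assignment for scanned dehydrin candidates.

Candidates with at least one above-threshold K segment are pattern-matched on
their structural formula into one of thirteen groups (K1, Kn, SKn, KnS, HKn,
HKnS, FKn, FSKn, YnKn, YnSKn, irregular, pseudo, reticulon) and mapped onto
the three phylogenetically defined orders F(S)Kn, Yn(S)Kn and (H)KnS.

Two screens demote candidates that are unlikely to be functional dehydrins:

* pseudo screen — K1/Kn/KnS/irregular candidates whose best K segment scores
  below 7.0 keep only weak, doubtfully functional K-like segments;
* reticulon screen — a fused K+serine-run segment near the N terminus,
  without a terminal S segment, is the hallmark of plant reticulons, which
  carry a K-like region but are not dehydrins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .config import RunConfig
from .scanner import Architecture, SegmentHit

GROUPS = (
    "K1", "Kn", "SKn", "KnS", "HKn", "HKnS", "FKn", "FSKn",
    "YnKn", "YnSKn", "irregular", "pseudo", "reticulon",
)

ORDERS = ("F(S)Kn", "Yn(S)Kn", "(H)KnS", "unassigned")

#: groups whose members may be demoted by the pseudo screen
_PSEUDO_ELIGIBLE = frozenset({"K1", "Kn", "KnS", "irregular"})

_PATTERNS = (
    (re.compile(r"^K$"), "K1"),
    (re.compile(r"^K{2,}$"), "Kn"),
    (re.compile(r"^SK+$"), "SKn"),
    (re.compile(r"^K+S$"), "KnS"),      # requires terminal S, checked below
    (re.compile(r"^HK+$"), "HKn"),
    (re.compile(r"^HK+S$"), "HKnS"),    # requires terminal S, checked below
    (re.compile(r"^F+K+$"), "FKn"),
    (re.compile(r"^F+SK+$"), "FSKn"),
    (re.compile(r"^Y+K+$"), "YnKn"),
    (re.compile(r"^Y+SK+$"), "YnSKn"),
)


@dataclass
class Classification:
    group: str
    order: str
    max_k_score: float
    flags: set[str] = field(default_factory=set)


def has_terminal_s(architecture: Architecture, config: RunConfig | None = None) -> bool:
    """True when the last hit is an S segment ending near the C terminus."""
    config = config or RunConfig()
    if not architecture.hits:
        return False
    last = architecture.hits[-1]
    return (
        last.segment_type == "S"
        and len(architecture.sequence) - last.end <= config.cterm_s_window
    )


def _match_letters(letters: str, terminal_s: bool) -> str:
    for pattern, group in _PATTERNS:
        if pattern.match(letters):
            if group in ("KnS", "HKnS") and not terminal_s:
                return "irregular"
            return group
    return "irregular"


def assign_group(
    architecture: Architecture, config: RunConfig | None = None
) -> str | None:
    """Pattern-match the formula into a group; None when no K hit (not a Dhn).

    Irregular candidates are re-evaluated once with hits scoring within 10%
    above their type threshold ignored; if a main-type formula emerges it is
    adopted (automated surrogate for manual curation of low-scoring segments).
    """
    config = config or RunConfig()
    scored = [h for h in architecture.hits if not h.inferred]
    if not any(h.segment_type == "K" for h in scored):
        return None
    letters = "".join(h.segment_type for h in scored)
    group = _match_letters(letters, has_terminal_s(architecture, config))
    if group == "irregular":
        strong = [
            h for h in scored
            if h.score >= 1.1 * config.threshold(h.segment_type)
        ]
        if strong and any(h.segment_type == "K" for h in strong):
            sub = Architecture(architecture.sequence, strong)
            rescued = _match_letters(
                "".join(h.segment_type for h in strong),
                has_terminal_s(sub, config),
            )
            if rescued != "irregular":
                return rescued
    return group


def max_k_score(architecture: Architecture) -> float:
    scores = [
        h.score for h in architecture.hits
        if h.segment_type == "K" and not h.inferred
    ]
    return max(scores, default=0.0)


def detect_reticulon(
    architecture: Architecture, config: RunConfig | None = None
) -> bool:
    """Detect the reticulon-style fused K+S-run near the N terminus.

    True iff some K hit starting within ``reticulon_window`` residues of the
    N terminus is followed, within ``reticulon_gap`` residues, by a run of at
    least ``reticulon_run`` S-dominated residues (S/D/E with a serine
    majority), and the sequence lacks a terminal S segment.
    """
    config = config or RunConfig()
    if has_terminal_s(architecture, config):
        return False
    sequence = architecture.sequence
    for hit in architecture.hits_of("K"):
        if hit.inferred or hit.start >= config.reticulon_window:
            continue
        for gap in range(config.reticulon_gap + 1):
            j = hit.end + gap
            if j >= len(sequence) or sequence[j] != "S":
                continue
            k = j
            while k < len(sequence) and sequence[k] in "SDE":
                k += 1
            run = sequence[j:k]
            n_ser = run.count("S")
            if n_ser >= config.reticulon_run and n_ser * 2 >= len(run):
                return True
            break
    return False


def assign_order(group: str, architecture: Architecture | None = None,
                 config: RunConfig | None = None) -> str:
    """Map a group onto one of the three phylogenetic orders.

    F-containing groups belong to F(S)Kn, Y-containing to Yn(S)Kn, and
    H-containing plus the uncommon KnS to (H)KnS.  Kn (incl. K1), SKn,
    pseudo and reticulon sequences stay unassigned; irregular sequences are
    placed by the accessory segments they actually contain.
    """
    if group in ("FKn", "FSKn"):
        return "F(S)Kn"
    if group in ("YnKn", "YnSKn"):
        return "Yn(S)Kn"
    if group in ("HKn", "HKnS", "KnS"):
        return "(H)KnS"
    if group == "irregular" and architecture is not None:
        present = {h.segment_type for h in architecture.hits}
        if "F" in present:
            return "F(S)Kn"
        if "Y" in present:
            return "Yn(S)Kn"
        if "H" in present or has_terminal_s(architecture, config):
            return "(H)KnS"
    return "unassigned"


def classify(
    architecture: Architecture,
    config: RunConfig | None = None,
    partial: bool = False,
) -> Classification | None:
    """Full group/order classification with pseudo and reticulon screens.

    Returns None for sequences without any K hit (not dehydrin candidates).
    """
    config = config or RunConfig()
    group = assign_group(architecture, config)
    if group is None:
        return None
    best_k = max_k_score(architecture)
    if detect_reticulon(architecture, config):
        group = "reticulon"
    elif group in _PSEUDO_ELIGIBLE and best_k < config.pseudo_k_cutoff:
        group = "pseudo"
    flags: set[str] = set()
    if partial:
        flags.add("partial")
    if any(
        h.segment_type == "F" and h.sequence[:2].startswith("GC")
        for h in architecture.hits
    ):
        flags.add("gc_variant_f")
    order = assign_order(group, architecture, config)
    return Classification(group=group, order=order, max_k_score=best_k,
                          flags=flags)


def fold_k1(group: str) -> str:
    """Fold K1 into Kn for downstream statistics (post-screen convention)."""
    return "Kn" if group == "K1" else group
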