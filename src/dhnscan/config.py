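"""Run configuration: segment thresholds, screening windows, repeat parameters.

Defaults follow the published operating point of the scan: acceptance
thresholds 6.0 (K, both tables), 6.8 (H), 5.0 (F), 3.5 (Y) and 5.2 (S); a
pseudo-dehydrin cutoff of 7.0 on the best K-segment score; and repeat seeds of
6 and 10 residues at 80% identity with at least 3 copies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class RunConfig:
    k_threshold: float = 6.0
    kvariant_threshold: float = 6.0
    h_threshold: float = 6.8
    f_threshold: float = 5.0
    y_threshold: float = 3.5
    s_threshold: float = 5.2
    #: K1/Kn/KnS/irregular candidates whose best K segment scores below this
    #: are demoted to provisional pseudo-dehydrin status.
    pseudo_k_cutoff: float = 7.0
    #: S seeds must reach this fraction of the S threshold on their first five
    #: residues before extension is attempted.
    s_seed_fraction: float = 0.5
    #: an S hit ending within this many residues of the C terminus counts as a
    #: terminal S segment (KnS/HKnS assignment).
    cterm_s_window: int = 10
    #: reticulon screen: fused K must start within this many residues of the
    #: N terminus ...
    reticulon_window: int = 60
    #: ... with an S-dominated run beginning within this many residues of the
    #: K segment end ...
    reticulon_gap: int = 3
    #: ... containing at least this many serines.
    reticulon_run: int = 4
    repeat_seed_lengths: tuple[int, ...] = (6, 10)
    repeat_min_identity: float = 0.8
    repeat_min_copies: int = 3
    repeat_extend: bool = False
    pseudocount: float = 0.01
    #: directory of TSV frequency tables overriding the bundled defaults
    table_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "k_threshold", "kvariant_threshold", "h_threshold",
            "f_threshold", "y_threshold", "s_threshold", "pseudo_k_cutoff",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.repeat_min_identity <= 1:
            raise ValueError("repeat_min_identity must be in (0, 1]")
        if self.repeat_min_copies < 1:
            raise ValueError("repeat_min_copies must be >= 1")
        self.repeat_seed_lengths = tuple(int(x) for x in self.repeat_seed_lengths)

    def threshold(self, segment_type: str) -> float:
        return {
            "K": self.k_threshold,
            "Kvariant": self.kvariant_threshold,
            "H": self.h_threshold,
            "F": self.f_threshold,
            "Y": self.y_threshold,
            "S": self.s_threshold,
        }[segment_type]

    # -- key=value config file -------------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = []
        for key, value in asdict(self).items():
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{key} = {value}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = value
        return cls(**{k: _coerce(k, v) for k, v in values.items()})


def _coerce(key: str, value: object):
    field_type = RunConfig.__dataclass_fields__[key].type
    text = str(value)
    if key == "repeat_seed_lengths":
        return tuple(int(v) for v in text.split(","))
    if key == "table_dir":
        return None if text in ("None", "") else text
    if "bool" in field_type:
        return text.lower() in ("1", "true", "yes")
    if "int" in field_type:
        return int(text)
    return float(text)
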