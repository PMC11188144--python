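"""Shared domain types."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple


@dataclass(frozen=True)
class ReferenceGenome:
    """One reference genome: identifier, sequence, and marker annotations.

    ``markers`` maps marker family number -> (start, end), 0-based half-open
    on the genome sequence.  Families are single-copy: at most one interval
    per family.
    """

    genome_id: str
    sequence: str
    markers: Dict[int, Tuple[int, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequence)

    def marker_sequence(self, family: int) -> str:
        start, end = self.markers[family]
        return self.sequence[start:end]


@dataclass(frozen=True)
class Read:
    """A sequencing read. ``mate`` is 0 for unpaired, 1 or 2 for pair members."""

    read_id: str
    sequence: str
    quality: str = ""
    mate: int = 0

    def __len__(self) -> int:
        return len(self.sequence)
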