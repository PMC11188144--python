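"""Sample-specific reference selection.

Reads are aligned to marker-cluster representative sequences only; each
representative's coverage is inherited by every member gene of its cluster.
A marker family counts as covered for a genome when breadth on the
representative strictly exceeds the breadth threshold, and a genome is
selected when at least ``min_fraction`` of the fixed family complement is
covered (inclusive threshold, per the differing wording of the two rules).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

from .align import TargetIndex, breadth, coverage_track, map_reads
from .markers import MarkerIndex
from .model import Read

DEFAULT_MIN_MARKER_FRACTION = 0.75
DEFAULT_MARKER_BREADTH = 0.90  # strict: breadth must EXCEED this


class NoReferenceRecruited(Exception):
    """Raised when no genome clears the marker-coverage bar.

    Signals a graceful pipeline stop, not a crash: the sample simply has no
    usable reference in the collection.
    """


@dataclass(frozen=True)
class MarkerCoverageProfile:
    genome_id: str
    covered_families: frozenset
    family_total: int

    @property
    def fraction_covered(self) -> float:
        return len(self.covered_families) / self.family_total


def screen_markers(
    reads: Sequence[Read],
    index: MarkerIndex,
    min_identity: float = 0.85,
    seed_length: int = 21,
    breadth_threshold: float = DEFAULT_MARKER_BREADTH,
) -> List[MarkerCoverageProfile]:
    """Map reads to representatives; derive per-genome marker coverage profiles.

    A read may hit representatives of several clusters (multi-target mapping);
    coverage of a representative is shared by all member genes of its cluster.
    """
    if not index.representatives:
        raise ValueError("marker index is empty")
    # mapping targets carry genome flanks so reads straddling a gene edge
    # still place; breadth is judged on the gene interval only
    rep_seqs = {rep.rep_id: rep.flanked_sequence for rep in index.representatives}
    tindex = TargetIndex(rep_seqs, seed_length)
    alignments = map_reads(
        reads, rep_seqs, min_identity=min_identity, seed_length=seed_length, index=tindex
    )

    by_target: Dict[str, list] = {}
    for a in alignments:
        by_target.setdefault(a.target_id, []).append(a)

    covered: Dict[str, Set[int]] = {}
    genome_ids: Set[str] = set()
    for rep in index.representatives:
        members = index.membership[rep.key]
        genome_ids.update(m.genome_id for m in members)
        rep_alignments = by_target.get(rep.rep_id, [])
        if rep_alignments:
            track = coverage_track(
                rep_alignments, len(rep.flanked_sequence), rep.rep_id
            )
            b = breadth(track, rep.gene_interval_in_flanked)
        else:
            b = 0.0
        if b > breadth_threshold:
            for member in members:
                covered.setdefault(member.genome_id, set()).add(member.marker_family)

    return [
        MarkerCoverageProfile(
            genome_id=gid,
            covered_families=frozenset(covered.get(gid, set())),
            family_total=index.family_count,
        )
        for gid in sorted(genome_ids)
    ]


def select_references(
    profiles: Sequence[MarkerCoverageProfile],
    min_fraction: float = DEFAULT_MIN_MARKER_FRACTION,
) -> List[str]:
    """Genome ids clearing the marker-fraction bar, best-covered first.

    An empty result is a legal outcome; the pipeline turns it into a graceful
    "no reference recruited" stop (NoReferenceRecruited).
    """
    chosen = [p for p in profiles if p.fraction_covered >= min_fraction]
    chosen.sort(key=lambda p: (-p.fraction_covered, p.genome_id))
    return [p.genome_id for p in chosen]


def profile_table(profiles: Sequence[MarkerCoverageProfile]) -> List[dict]:
    return [
        {
            "genome_id": p.genome_id,
            "families_covered": len(p.covered_families),
            "family_total": p.family_total,
            "fraction": f"{p.fraction_covered:.4f}",
        }
        for p in sorted(profiles, key=lambda p: (-p.fraction_covered, p.genome_id))
    ]
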