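"""Greedy reference-guided assembly within one genome cluster.

Genomes in a cluster are visited in order of sketch containment with the
still-unassigned reads (a greedy set-cover heuristic: pick the reference that
explains the most remaining reads).  Against each guide, reads are aligned,
covered runs of the guide become contigs (runs shorter than the minimum are
dropped and their reads stay unassigned), and the run stops at the first of
four termination criteria:

  i.   all reads assembled;
  ii.  all references in the cluster assembled;
  iii. the last guide's cumulative contig length below 5% of that guide;
  iv.  the last guide's longest contig shorter than 2 kb.

When iii or iv fires in a multi-genome cluster the last guide's result is
discarded and its reads returned to the pool; a singleton cluster always
retains its (only) result, which falls out of the i..iv check order because
criterion ii fires first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .align import ReadAlignment, TargetIndex, coverage_track, covered_runs, map_reads
from .cull import GenomeCluster, genome_sketch
from .metrics import ng25
from .model import Read, ReferenceGenome
from .sketch import DEFAULT_HASH_SEED, KmerSet, Sketch, build_kmer_set, containment

DEFAULT_MIN_CONTIG = 500
DEFAULT_MIN_LONGEST_CONTIG = 2000
DEFAULT_MIN_CUMULATIVE_FRACTION = 0.05

STOP_NONE = "none"
STOP_ALL_READS = "all_reads_assembled"
STOP_ALL_REFS = "all_references_assembled"
STOP_CUMULATIVE = "cumulative_below_5pct"
STOP_LONGEST = "longest_below_2kb"


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    guide_genome_id: str
    guide_interval: Tuple[int, int]  # 0-based half-open, pre-polish
    supporting_read_ids: FrozenSet[str]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AGPRecord:
    """One AGP v2.1 row: a contig (W) or gap (N) part tiling the guide."""

    object_id: str
    object_start: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # "W" or "N"
    component_id: str = ""  # W only
    gap_length: int = 0  # N only

    def to_fields(self) -> List[str]:
        if self.component_type == "W":
            length = self.object_end - self.object_start + 1
            return [
                self.object_id,
                str(self.object_start),
                str(self.object_end),
                str(self.part_number),
                "W",
                self.component_id,
                "1",
                str(length),
                "+",
            ]
        return [
            self.object_id,
            str(self.object_start),
            str(self.object_end),
            str(self.part_number),
            "N",
            str(self.gap_length),
            "contig",
            "no",
            "align_genus",
        ]


@dataclass
class ClusterAssemblyState:
    cluster_id: int
    remaining_genomes: List[str]
    unassigned_read_ids: Set[str]
    contigs: List[Contig] = field(default_factory=list)
    stop_reason: str = STOP_NONE


@dataclass
class GuideResult:
    """Assembly outcome against a single guide genome."""

    guide_id: str
    contigs: List[Contig]
    agp: List[AGPRecord]
    used_read_ids: Set[str]
    contig_alignments: Dict[str, List[ReadAlignment]]


def order_next_genome(
    state: ClusterAssemblyState,
    read_kmers: KmerSet,
    sketches: Dict[str, Sketch],
    genome_lengths: Dict[str, int],
) -> str:
    """Remaining genome with maximal sketch containment in the unassigned reads.

    Ties break to the longer genome, then to the lexicographically smaller id.
    """
    if not state.remaining_genomes:
        raise ValueError("no genomes remain in cluster")

    def rank(gid: str):
        c = containment(sketches[gid], read_kmers) if len(read_kmers) else 0.0
        return (-c, -genome_lengths[gid], gid)

    return min(state.remaining_genomes, key=rank)


def assemble_against_reference(
    reads: Sequence[Read],
    guide: ReferenceGenome,
    min_contig: int = DEFAULT_MIN_CONTIG,
    min_identity: float = 0.85,
    seed_length: int = 21,
) -> GuideResult:
    """Align reads to the guide and cut contigs from the covered runs.

    A maximal run of depth >= 1 becomes a contig carrying the guide sequence
    over the run; runs shorter than ``min_contig`` are dropped and their reads
    are NOT marked used.  AGP records tile the full guide, alternating contig
    (W) and gap (N) parts.
    """
    alignments = map_reads(
        reads,
        {guide.genome_id: guide.sequence},
        min_identity=min_identity,
        seed_length=seed_length,
    )
    glen = len(guide.sequence)
    track = coverage_track(alignments, glen, guide.genome_id)
    runs = covered_runs(track)

    kept = [(s, e) for s, e in runs if e - s >= min_contig]
    kept_idx = {run: i for i, run in enumerate(kept, start=1)}

    # every alignment interval is fully covered (by itself), hence inside
    # exactly one maximal run
    per_run: Dict[Tuple[int, int], List[ReadAlignment]] = {run: [] for run in kept}
    run_starts = [s for s, _ in runs]
    import bisect

    for a in alignments:
        i = bisect.bisect_right(run_starts, a.start) - 1
        run = runs[i]
        if run in per_run:
            per_run[run].append(a)

    contigs: List[Contig] = []
    contig_alignments: Dict[str, List[ReadAlignment]] = {}
    used: Set[str] = set()
    for run in kept:
        s, e = run
        cid = f"{guide.genome_id}_{kept_idx[run]}"
        support = frozenset(a.read_id for a in per_run[run])
        used |= set(support)
        contigs.append(
            Contig(
                contig_id=cid,
                sequence=guide.sequence[s:e],
                guide_genome_id=guide.genome_id,
                guide_interval=run,
                supporting_read_ids=support,
            )
        )
        # shift alignments into contig coordinates for downstream polishing
        contig_alignments[cid] = [
            ReadAlignment(
                read_id=a.read_id,
                target_id=cid,
                start=a.start - s,
                end=a.end - s,
                strand=a.strand,
                matches=a.matches,
                aligned_length=a.aligned_length,
                edits=tuple((p - s, b) for p, b in a.edits),
            )
            for a in per_run[run]
        ]

    agp = build_agp(guide.genome_id, glen, contigs)
    return GuideResult(
        guide_id=guide.genome_id,
        contigs=contigs,
        agp=agp,
        used_read_ids=used,
        contig_alignments=contig_alignments,
    )


def build_agp(object_id: str, object_length: int, contigs: Sequence[Contig]) -> List[AGPRecord]:
    """W/N records tiling 1..object_length, coordinates strictly increasing."""
    records: List[AGPRecord] = []
    part = 0
    cursor = 0  # 0-based
    for contig in sorted(contigs, key=lambda c: c.guide_interval):
        s, e = contig.guide_interval
        if s > cursor:
            part += 1
            records.append(
                AGPRecord(object_id, cursor + 1, s, part, "N", gap_length=s - cursor)
            )
        part += 1
        records.append(AGPRecord(object_id, s + 1, e, part, "W", component_id=contig.contig_id))
        cursor = e
    if cursor < object_length:
        part += 1
        records.append(
            AGPRecord(
                object_id, cursor + 1, object_length, part, "N",
                gap_length=object_length - cursor,
            )
        )
    return records


def check_termination(
    state: ClusterAssemblyState,
    last_result: GuideResult,
    guide_length: int,
    cluster_size: int,
    min_cumulative_fraction: float = DEFAULT_MIN_CUMULATIVE_FRACTION,
    min_longest_contig: int = DEFAULT_MIN_LONGEST_CONTIG,
) -> Tuple[str, bool]:
    """Evaluate criteria i..iv after a guide assembly.

    Returns (stop_reason_or_"continue", retain_last_result).  Criteria iii
    and iv are judged on the last guide only: cumulative contig length versus
    that guide's length, and that guide's longest contig.  Singleton clusters
    always retain the result.
    """
    if not state.unassigned_read_ids:
        return STOP_ALL_READS, True
    if not state.remaining_genomes:
        return STOP_ALL_REFS, True
    cumulative = sum(len(c) for c in last_result.contigs)
    longest = max((len(c) for c in last_result.contigs), default=0)
    if cumulative < min_cumulative_fraction * guide_length:
        return STOP_CUMULATIVE, cluster_size == 1
    if longest < min_longest_contig:
        return STOP_LONGEST, cluster_size == 1
    return "continue", True


def assemble_cluster(
    cluster: GenomeCluster,
    reads: Sequence[Read],
    genomes: Dict[str, ReferenceGenome],
    k_sketch: int = 21,
    sketch_size: int = 1000,
    hash_seed: int = DEFAULT_HASH_SEED,
    min_contig: int = DEFAULT_MIN_CONTIG,
    min_identity: float = 0.85,
    seed_length: int = 21,
    min_cumulative_fraction: float = DEFAULT_MIN_CUMULATIVE_FRACTION,
    min_longest_contig: int = DEFAULT_MIN_LONGEST_CONTIG,
) -> Tuple[List[Contig], List[AGPRecord], Set[str], List[dict], ClusterAssemblyState, Dict[str, List[ReadAlignment]]]:
    """Run the greedy per-cluster loop: order -> assemble -> check termination.

    Returns (contigs, agp, used_read_ids, per-genome log rows, final state,
    contig alignments for polishing).
    """
    cluster_size = len(cluster.genome_ids)
    sketches = {
        gid: genome_sketch(genomes[gid], k_sketch, sketch_size, hash_seed)
        for gid in cluster.genome_ids
    }
    lengths = {gid: len(genomes[gid].sequence) for gid in cluster.genome_ids}
    by_id = {r.read_id: r for r in reads}

    state = ClusterAssemblyState(
        cluster_id=cluster.cluster_id,
        remaining_genomes=list(cluster.genome_ids),
        unassigned_read_ids=set(by_id),
    )
    all_agp: List[AGPRecord] = []
    all_alignments: Dict[str, List[ReadAlignment]] = {}
    used_total: Set[str] = set()
    log: List[dict] = []

    while state.remaining_genomes and state.unassigned_read_ids:
        pool = [by_id[rid] for rid in sorted(state.unassigned_read_ids)]
        read_kmers = build_kmer_set(
            [r.sequence for r in pool], k_sketch, source_id="unassigned", seed=hash_seed
        )
        gid = order_next_genome(state, read_kmers, sketches, lengths)
        state.remaining_genomes.remove(gid)

        result = assemble_against_reference(
            pool, genomes[gid], min_contig, min_identity, seed_length
        )
        # tentatively consume, then let iii/iv roll back
        state.unassigned_read_ids -= result.used_read_ids
        reason, retain = check_termination(
            state, result, lengths[gid], cluster_size,
            min_cumulative_fraction, min_longest_contig,
        )
        if retain:
            state.contigs.extend(result.contigs)
            all_agp.extend(result.agp)
            all_alignments.update(result.contig_alignments)
            used_total |= result.used_read_ids
            log.append(_guide_log_row(cluster.cluster_id, gid, lengths[gid], result))
        else:
            state.unassigned_read_ids |= result.used_read_ids
            row = _guide_log_row(cluster.cluster_id, gid, lengths[gid], result)
            row["retained"] = "no"
            log.append(row)
        if reason != "continue":
            state.stop_reason = reason
            break
    else:
        state.stop_reason = (
            STOP_ALL_READS if not state.unassigned_read_ids else STOP_ALL_REFS
        )

    return state.contigs, all_agp, used_total, log, state, all_alignments


def _guide_log_row(cluster_id: int, gid: str, guide_length: int, result: GuideResult) -> dict:
    lengths = [len(c) for c in result.contigs]
    bases = sum(lengths)
    n = ng25(lengths, guide_length)
    return {
        "cluster_id": cluster_id,
        "genome_id": gid,
        "bases_assembled": bases,
        "pct_of_guide": f"{100.0 * bases / guide_length:.2f}",
        "contigs_gt_2kb": sum(1 for x in lengths if x > 2000),
        "longest_contig": max(lengths, default=0),
        "ng25": n if n is not None else "undefined",
        "retained": "yes",
    }
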