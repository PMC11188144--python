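"""End-to-end orchestration: screen -> select -> cull -> cluster-by-cluster
guided assembly -> polish, plus the standard output files and run summary.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from . import io as gio
from .assembly import AGPRecord, Contig, assemble_cluster
from .config import PipelineConfig
from .cull import GenomeCluster, cluster_by_ani, cluster_table, next_cluster
from .markers import MarkerIndex, build_marker_index
from .metrics import fraction_reads_mapped, ng25
from .model import Read, ReferenceGenome
from .polish import PolishReport, polish_contig, write_change_report
from .select import (
    NoReferenceRecruited,
    profile_table,
    screen_markers,
    select_references,
)
from .sketch import build_kmer_set

logger = logging.getLogger("guideasm")


@dataclass
class RunSummary:
    total_reads: int
    used_reads: int
    no_reference: bool = False
    references_used: List[str] = field(default_factory=list)
    contig_count: int = 0
    total_bases_assembled: int = 0
    fraction_reads_mapped: float = 0.0
    cluster_logs: List[dict] = field(default_factory=list)
    genome_logs: List[dict] = field(default_factory=list)
    stop_reasons: Dict[int, str] = field(default_factory=dict)
    ng25_per_guide: Dict[str, Optional[int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "used_reads": self.used_reads,
            "no_reference": self.no_reference,
            "references_used": self.references_used,
            "contig_count": self.contig_count,
            "total_bases_assembled": self.total_bases_assembled,
            "fraction_reads_mapped": self.fraction_reads_mapped,
            "stop_reasons": {str(k): v for k, v in self.stop_reasons.items()},
            "ng25_per_guide": self.ng25_per_guide,
            "genome_logs": self.genome_logs,
            "cluster_logs": self.cluster_logs,
        }


@dataclass
class PipelineResult:
    summary: RunSummary
    contigs: List[Contig]
    polished: Dict[str, str]  # contig_id -> polished sequence
    agp: List[AGPRecord]
    polish_reports: List[PolishReport]
    used_read_ids: Set[str]
    unused_read_ids: Set[str]
    clusters: List[GenomeCluster] = field(default_factory=list)


def run_pipeline(
    reads: Sequence[Read],
    genomes: Sequence[ReferenceGenome],
    config: PipelineConfig = None,
    marker_index: MarkerIndex = None,
    outdir=None,
) -> PipelineResult:
    """Execute the full pipeline; optionally write all standard outputs.

    With no recruitable reference the run stops gracefully: the summary is
    flagged ``no_reference``, and every input read is reported unused.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    by_id: Dict[str, ReferenceGenome] = {g.genome_id: g for g in genomes}
    all_read_ids = {r.read_id for r in reads}
    reads_by_id = {r.read_id: r for r in reads}
    if len(reads_by_id) != len(reads):
        raise ValueError("duplicate read ids in input")

    if marker_index is None:
        marker_index = build_marker_index(
            genomes, config.marker_identity, config.marker_family_count
        )

    # --- reference selection -------------------------------------------------
    if reads:
        profiles = screen_markers(
            reads, marker_index,
            min_identity=config.min_identity,
            seed_length=config.seed_length,
            breadth_threshold=config.marker_breadth,
        )
        selected = select_references(profiles, config.min_marker_fraction)
    else:
        profiles, selected = [], []
    logger.info("selected %d/%d genomes (%.1fs)", len(selected), len(genomes), time.time() - t0)

    if not selected:
        summary = RunSummary(
            total_reads=len(reads), used_reads=0, no_reference=True,
            fraction_reads_mapped=0.0 if reads else 0.0,
        )
        result = PipelineResult(
            summary=summary, contigs=[], polished={}, agp=[], polish_reports=[],
            used_read_ids=set(), unused_read_ids=set(all_read_ids),
        )
        if outdir is not None:
            _write_outputs(result, reads_by_id, profiles, [], {}, outdir)
        return result

    # --- culling -------------------------------------------------------------
    clusters = cluster_by_ani(
        [by_id[g] for g in selected],
        ani_threshold=config.ani_threshold,
        k_sketch=config.k_sketch,
        sketch_size=config.sketch_size,
        k_intersection=config.k_intersection,
        seed=config.hash_seed,
    )
    logger.info("culled %d genomes into %d clusters", len(selected), len(clusters))

    # --- prioritized cluster assembly ---------------------------------------
    unassigned: Set[str] = set(all_read_ids)
    pending = list(clusters)
    order: Dict[int, int] = {}
    all_contigs: List[Contig] = []
    all_agp: List[AGPRecord] = []
    genome_logs: List[dict] = []
    stop_reasons: Dict[int, str] = {}
    polished: Dict[str, str] = {}
    polish_reports: List[PolishReport] = []
    ordinal = 0

    while pending and unassigned:
        pool_reads = [reads_by_id[rid] for rid in sorted(unassigned)]
        pool_kmers = build_kmer_set(
            [r.sequence for r in pool_reads], config.k_intersection,
            source_id="unassigned", seed=config.hash_seed,
        )
        cluster = next_cluster(pending, pool_kmers)
        if cluster is None:
            break
        ordinal += 1
        order[cluster.cluster_id] = ordinal
        pending = [c for c in pending if c.cluster_id != cluster.cluster_id]

        contigs, agp, used, log, state, contig_alignments = assemble_cluster(
            cluster, pool_reads, by_id,
            k_sketch=config.k_sketch, sketch_size=config.sketch_size,
            hash_seed=config.hash_seed, min_contig=config.min_contig,
            min_identity=config.min_identity, seed_length=config.seed_length,
            min_cumulative_fraction=config.min_cumulative_fraction,
            min_longest_contig=config.min_longest_contig,
        )
        unassigned -= used
        all_contigs.extend(contigs)
        all_agp.extend(agp)
        genome_logs.extend(log)
        stop_reasons[cluster.cluster_id] = state.stop_reason
        logger.info(
            "cluster %d: %d contigs, %d reads used, stop=%s",
            cluster.cluster_id, len(contigs), len(used), state.stop_reason,
        )

        for contig in contigs:
            support = [reads_by_id[rid] for rid in sorted(contig.supporting_read_ids)]
            seq, report = polish_contig(
                contig.sequence, support, contig.contig_id,
                min_identity=config.min_identity, seed_length=config.seed_length,
                min_depth=config.polish_min_depth, majority=config.polish_majority,
                max_indel=config.polish_max_indel,
            )
            polished[contig.contig_id] = seq
            polish_reports.append(report)

    used_ids = all_read_ids - unassigned
    summary = RunSummary(
        total_reads=len(reads),
        used_reads=len(used_ids),
        references_used=sorted({c.guide_genome_id for c in all_contigs}),
        contig_count=len(all_contigs),
        total_bases_assembled=sum(len(c) for c in all_contigs),
        fraction_reads_mapped=fraction_reads_mapped(len(used_ids), len(reads)),
        genome_logs=genome_logs,
        cluster_logs=cluster_table(clusters, order),
        stop_reasons=stop_reasons,
        ng25_per_guide=_ng25_per_guide(all_contigs, by_id),
    )
    result = PipelineResult(
        summary=summary, contigs=all_contigs, polished=polished, agp=all_agp,
        polish_reports=polish_reports, used_read_ids=used_ids,
        unused_read_ids=unassigned, clusters=clusters,
    )
    _assert_read_conservation(result, all_read_ids)
    if outdir is not None:
        _write_outputs(result, reads_by_id, profiles, clusters, order, outdir)
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return result


def _ng25_per_guide(contigs: Sequence[Contig], by_id: Dict[str, ReferenceGenome]) -> Dict[str, Optional[int]]:
    per_guide: Dict[str, List[int]] = {}
    for c in contigs:
        per_guide.setdefault(c.guide_genome_id, []).append(len(c))
    return {
        gid: ng25(lengths, len(by_id[gid].sequence))
        for gid, lengths in sorted(per_guide.items())
    }


def _assert_read_conservation(result: PipelineResult, all_read_ids: Set[str]) -> None:
    if result.used_read_ids & result.unused_read_ids:
        raise AssertionError("read appears both used and unused")
    if result.used_read_ids | result.unused_read_ids != all_read_ids:
        raise AssertionError("used + unused reads do not reproduce the input")


def _write_outputs(
    result: PipelineResult,
    reads_by_id: Dict[str, Read],
    profiles,
    clusters,
    order: Dict[int, int],
    outdir,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_fasta(
        ((c.contig_id, c.sequence) for c in result.contigs), outdir / "contigs.fasta"
    )
    gio.write_fasta(
        sorted(result.polished.items()), outdir / "contigs.polished.fasta"
    )
    gio.write_agp(result.agp, outdir / "assembly.agp")
    gio.write_table(
        profile_table(profiles),
        ["genome_id", "families_covered", "family_total", "fraction"],
        outdir / "marker_profiles.tsv",
    )
    gio.write_table(
        [{"genome_id": g} for g in result.summary.references_used],
        ["genome_id"],
        outdir / "references_used.tsv",
    )
    if clusters:
        gio.write_table(
            cluster_table(clusters, order),
            ["cluster_id", "members", "longest_member", "priority", "order_processed"],
            outdir / "clusters.tsv",
        )
    if result.summary.genome_logs:
        gio.write_table(
            result.summary.genome_logs,
            ["cluster_id", "genome_id", "bases_assembled", "pct_of_guide",
             "contigs_gt_2kb", "longest_contig", "ng25", "retained"],
            outdir / "genome_log.tsv",
        )
    write_change_report(result.polish_reports, outdir / "polish_changes.tsv")
    gio.write_fastq(
        (reads_by_id[rid] for rid in sorted(result.unused_read_ids)),
        outdir / "unused_reads.fastq",
    )
    with open(outdir / "used_read_ids.txt", "w") as fh:
        for rid in sorted(result.used_read_ids):
            fh.write(rid + "\n")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(result.summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
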