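"""Species-level culling of the selected references.

Selected genomes are grouped into single-linkage connected components of the
pairwise ANI graph at the species threshold, and clusters are then processed
one at a time in order of their exact k-mer intersection with the pool of
still-unassigned reads, recomputed before every pick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import ReferenceGenome
from .sketch import (
    DEFAULT_HASH_SEED,
    KmerSet,
    Sketch,
    bottom_sketch,
    build_kmer_set,
    estimate_ani,
    kmer_intersection_size,
)

DEFAULT_ANI_THRESHOLD = 95.0
DEFAULT_K_SKETCH = 21
DEFAULT_SKETCH_SIZE = 1000
DEFAULT_K_INTERSECTION = 28


@dataclass
class GenomeCluster:
    cluster_id: int
    genome_ids: Tuple[str, ...]  # sorted
    longest_genome_id: str
    kmer_set: KmerSet  # union set at the intersection k
    priority: int = -1  # last-computed intersection with unassigned reads

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.genome_ids


def genome_sketch(
    genome: ReferenceGenome,
    k: int = DEFAULT_K_SKETCH,
    s: int = DEFAULT_SKETCH_SIZE,
    seed: int = DEFAULT_HASH_SEED,
) -> Sketch:
    return bottom_sketch(
        build_kmer_set([genome.sequence], k, source_id=genome.genome_id, seed=seed), s
    )


def pairwise_ani(
    genomes: Sequence[ReferenceGenome],
    k: int = DEFAULT_K_SKETCH,
    s: int = DEFAULT_SKETCH_SIZE,
    seed: int = DEFAULT_HASH_SEED,
) -> Dict[Tuple[str, str], Optional[float]]:
    """ANI estimate for every unordered genome pair (None = undetected)."""
    sketches = {g.genome_id: genome_sketch(g, k, s, seed) for g in genomes}
    out: Dict[Tuple[str, str], Optional[float]] = {}
    ids = sorted(sketches)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            out[(a, b)] = estimate_ani(sketches[a], sketches[b])
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def cluster_by_ani(
    genomes: Sequence[ReferenceGenome],
    ani_threshold: float = DEFAULT_ANI_THRESHOLD,
    k_sketch: int = DEFAULT_K_SKETCH,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
    k_intersection: int = DEFAULT_K_INTERSECTION,
    seed: int = DEFAULT_HASH_SEED,
) -> List[GenomeCluster]:
    """Single-linkage components of the >= ani_threshold graph.

    Cluster ids are assigned by lexicographically smallest member id, so the
    numbering is independent of input order.
    """
    if not genomes:
        raise ValueError("at least one genome required")
    by_id = {g.genome_id: g for g in genomes}
    uf = _UnionFind(sorted(by_id))
    for (a, b), ani in pairwise_ani(genomes, k_sketch, sketch_size, seed).items():
        if ani is not None and ani >= ani_threshold:
            uf.union(a, b)

    components: Dict[str, List[str]] = {}
    for gid in sorted(by_id):
        components.setdefault(uf.find(gid), []).append(gid)

    clusters = []
    for cid, root in enumerate(sorted(components), start=1):
        members = sorted(components[root])
        longest = max(members, key=lambda g: (len(by_id[g].sequence), g))
        kset = build_kmer_set(
            [by_id[g].sequence for g in members],
            k_intersection,
            source_id=f"cluster_{cid}",
            seed=seed,
        )
        clusters.append(
            GenomeCluster(
                cluster_id=cid,
                genome_ids=tuple(members),
                longest_genome_id=longest,
                kmer_set=kset,
            )
        )
    return clusters


def next_cluster(
    clusters: Sequence[GenomeCluster], unassigned_reads: KmerSet
) -> Optional[GenomeCluster]:
    """Highest-priority unprocessed cluster, or None when all priorities are 0.

    Priority = exact k-mer intersection between the cluster's union k-mer set
    and the unassigned-read k-mer set; ties break to the smaller cluster_id.
    Each call recomputes every candidate's priority against the current pool.
    """
    best: Optional[GenomeCluster] = None
    for cluster in clusters:
        cluster.priority = kmer_intersection_size(cluster.kmer_set, unassigned_reads)
        if cluster.priority > 0 and (
            best is None
            or (cluster.priority, -cluster.cluster_id)
            > (best.priority, -best.cluster_id)
        ):
            best = cluster
    return best


def cluster_table(clusters: Sequence[GenomeCluster], order: Dict[int, int]) -> List[dict]:
    """Tabular cluster report; ``order`` maps cluster_id -> processing ordinal."""
    return [
        {
            "cluster_id": c.cluster_id,
            "members": ",".join(c.genome_ids),
            "longest_member": c.longest_genome_id,
            "priority": c.priority,
            "order_processed": order.get(c.cluster_id, "skipped"),
        }
        for c in clusters
    ]
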