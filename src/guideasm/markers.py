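"""Marker-gene index: extraction of annotated single-copy marker genes and
greedy per-family clustering at high identity, with cluster representatives
serving as the alignment targets for reference selection.

Clustering is greedy-incremental, longest-first: a gene joins the first
existing representative of its family it matches at >= the identity
threshold, otherwise it founds a new cluster.  Identity is defined exactly
(banded fit alignment, matches over the shorter length) so tests can use an
independent full-DP oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

from . import io as gio
from .model import ReferenceGenome
from .sketch import _encode

DEFAULT_MARKER_IDENTITY = 0.99
DEFAULT_FAMILY_COUNT = 40
BAND_FRACTION = 0.05
MIN_BAND = 5

NEG_INF = np.iinfo(np.int32).min // 2


FLANK_LENGTH = 150  # genome context kept around each gene for read mapping


@dataclass(frozen=True)
class MarkerGene:
    genome_id: str
    marker_family: int
    interval: Tuple[int, int]  # 0-based half-open on the genome
    sequence: str
    # flanking genome sequence so reads straddling a gene edge still map;
    # breadth is always judged on the gene interval proper
    flank_left: str = ""
    flank_right: str = ""

    @property
    def key(self) -> Tuple[str, int]:
        return (self.genome_id, self.marker_family)

    @property
    def flanked_sequence(self) -> str:
        return self.flank_left + self.sequence + self.flank_right

    @property
    def gene_interval_in_flanked(self) -> Tuple[int, int]:
        return (len(self.flank_left), len(self.flank_left) + len(self.sequence))

    @property
    def rep_id(self) -> str:
        """Stable identifier used as FASTA id / alignment target id."""
        return f"{self.genome_id}|fam{self.marker_family}"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MarkerIndex:
    representatives: List[MarkerGene]
    membership: Dict[Tuple[str, int], List[MarkerGene]]  # rep key -> members
    family_count: int = DEFAULT_FAMILY_COUNT
    identity_threshold: float = DEFAULT_MARKER_IDENTITY

    def all_genes(self) -> List[MarkerGene]:
        return [g for members in self.membership.values() for g in members]

    def representative_sequences(self) -> Dict[str, str]:
        return {rep.rep_id: rep.sequence for rep in self.representatives}


def load_marker_annotations(
    genomes: Sequence[ReferenceGenome] = None,
    fasta_paths: Sequence = None,
    annotation_path=None,
) -> List[MarkerGene]:
    """Materialize MarkerGenes from genome sequences plus interval annotations.

    Accepts either already-loaded ReferenceGenomes (whose ``markers`` carry
    the intervals) or FASTA path(s) plus an annotation table.  Out-of-bounds
    intervals and unknown genome ids are hard errors naming the offender.
    """
    if genomes is None:
        if fasta_paths is None or annotation_path is None:
            raise ValueError("provide genomes or fasta_paths + annotation_path")
        genomes = gio.load_reference_genomes(fasta_paths, annotation_path)
        annotated_ids = {g.genome_id for g in genomes if g.markers}
        known = {g.genome_id for g in genomes}
        for gid in gio.read_marker_annotations(annotation_path):
            if gid not in known:
                raise ValueError(f"annotation references unknown genome id {gid!r}")
    out: List[MarkerGene] = []
    for g in genomes:
        for family in sorted(g.markers):
            start, end = g.markers[family]
            if start < 0 or end > len(g.sequence):
                raise ValueError(
                    f"marker (genome={g.genome_id!r}, family={family}) interval "
                    f"[{start}, {end}) outside genome of length {len(g.sequence)}"
                )
            out.append(
                MarkerGene(
                    genome_id=g.genome_id,
                    marker_family=family,
                    interval=(start, end),
                    sequence=g.sequence[start:end],
                    flank_left=g.sequence[max(0, start - FLANK_LENGTH) : start],
                    flank_right=g.sequence[end : end + FLANK_LENGTH],
                )
            )
    return out


def banded_identity(a: str, b: str, band_fraction: float = BAND_FRACTION) -> float:
    """Identity of the shorter sequence fit-aligned to the longer one.

    Banded DP maximizing matched bases; leading/trailing gaps on the longer
    sequence are free; the diagonal shift is bounded by
    max(MIN_BAND, band_fraction * len(longer)).  Identity = max matches /
    len(shorter).
    """
    if len(a) > len(b):
        a, b = b, a
    m, n = len(a), len(b)
    if m == 0:
        return 0.0
    band = max(MIN_BAND, int(np.ceil(band_fraction * n)))
    dmin, dmax = -band, (n - m) + band
    width = dmax - dmin + 1

    ac = _encode(a).astype(np.int32)
    bc = _encode(b).astype(np.int32)
    ds = np.arange(dmin, dmax + 1)

    # H[d] = best matches aligning a[:i] ending at b position j = i + d
    H = np.where(ds >= 0, 0, NEG_INF)  # i = 0: free leading gap in b needs j >= 0
    for i in range(1, m + 1):
        j = i + ds  # b index (1-based) consumed by the diagonal move
        valid = (j >= 1) & (j <= n)
        match = np.full(width, NEG_INF, dtype=np.int64)
        bj = np.clip(j - 1, 0, n - 1)
        eq = (ac[i - 1] == bc[bj]) & (ac[i - 1] != 255)
        match[valid] = H[valid] + eq[valid]
        # gap in b (consume a only): from H[i-1][d+1]
        shifted = np.concatenate([H[1:], [NEG_INF]])
        gap_b = np.where(valid, shifted, NEG_INF)
        new = np.maximum(match, gap_b)
        # gap in a (consume b only): within-row scan H[i][d] >= H[i][d-1]
        new = np.maximum.accumulate(new)
        new[~valid & (j < 1)] = NEG_INF
        H = new
    tail = H[(m + ds >= 0) & (m + ds <= n)]
    best = int(tail.max()) if tail.size else 0
    return max(best, 0) / m


def greedy_identity_cluster(
    genes: Sequence[MarkerGene],
    identity_threshold: float = DEFAULT_MARKER_IDENTITY,
    family_count: int = DEFAULT_FAMILY_COUNT,
) -> MarkerIndex:
    """Greedy longest-first clustering, performed independently per family.

    Deterministic: candidate order is (length desc, genome_id asc, family asc);
    a gene is assigned to the first representative it matches.
    """
    if not genes:
        raise ValueError("gene list must be nonempty")
    by_family: Dict[int, List[MarkerGene]] = {}
    for g in genes:
        by_family.setdefault(g.marker_family, []).append(g)

    representatives: List[MarkerGene] = []
    membership: Dict[Tuple[str, int], List[MarkerGene]] = {}
    for family in sorted(by_family):
        ordered = sorted(
            by_family[family], key=lambda g: (-len(g), g.genome_id, g.marker_family)
        )
        reps: List[MarkerGene] = []
        for gene in ordered:
            home = None
            for rep in reps:
                if banded_identity(gene.sequence, rep.sequence) >= identity_threshold:
                    home = rep
                    break
            if home is None:
                reps.append(gene)
                membership[gene.key] = [gene]
            else:
                membership[home.key].append(gene)
        representatives.extend(reps)

    return MarkerIndex(
        representatives=representatives,
        membership=membership,
        family_count=family_count,
        identity_threshold=identity_threshold,
    )


def build_marker_index(
    genomes: Sequence[ReferenceGenome],
    identity_threshold: float = DEFAULT_MARKER_IDENTITY,
    family_count: int = DEFAULT_FAMILY_COUNT,
) -> MarkerIndex:
    genes = load_marker_annotations(genomes=genomes)
    return greedy_identity_cluster(genes, identity_threshold, family_count)


# ---------------------------------------------------------------------------
# persistence: FASTA of representatives + membership table, reusable per run


def save_marker_index(index: MarkerIndex, fasta_path, membership_path) -> None:
    gio.write_fasta(
        ((rep.rep_id, rep.sequence) for rep in index.representatives), fasta_path
    )
    rows = []
    for rep in index.representatives:
        for member in index.membership[rep.key]:
            rows.append(
                {
                    "representative": rep.rep_id,
                    "genome_id": member.genome_id,
                    "family": member.marker_family,
                    "start": member.interval[0],
                    "end": member.interval[1],
                }
            )
    gio.write_table(
        rows, ["representative", "genome_id", "family", "start", "end"], membership_path
    )


def load_marker_index(
    fasta_path, membership_path, genomes: Sequence[ReferenceGenome]
) -> MarkerIndex:
    rep_seqs = gio.read_fasta(fasta_path)
    by_id = {g.genome_id: g for g in genomes}
    membership: Dict[Tuple[str, int], List[MarkerGene]] = {}
    reps: Dict[str, MarkerGene] = {}
    with open(membership_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            gseq = by_id[row["genome_id"]].sequence
            start, end = int(row["start"]), int(row["end"])
            gene = MarkerGene(
                genome_id=row["genome_id"],
                marker_family=int(row["family"]),
                interval=(start, end),
                sequence=gseq[start:end],
                flank_left=gseq[max(0, start - FLANK_LENGTH) : start],
                flank_right=gseq[end : end + FLANK_LENGTH],
            )
            rep_id = row["representative"]
            if rep_id not in reps and gene.rep_id == rep_id:
                reps[rep_id] = gene
            membership.setdefault(rep_id, []).append(gene)
    representatives = [reps[rid] for rid in rep_seqs if rid in reps]
    return MarkerIndex(
        representatives=representatives,
        membership={rep.key: membership[rep.rep_id] for rep in representatives},
        family_count=DEFAULT_FAMILY_COUNT,
    )
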