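"""Seeded synthetic communities with exact ground truth.

Everything is generated from numpy Generators seeded explicitly, so a fixed
seed yields byte-identical genomes, reads and truth tables on any platform.

A community consists of species genomes (mutually unrelated random sequence),
optional within-species strain references, and per-genome "sample strains" —
the sequences actually sequenced, possibly diverged from their reference.
Every genome carries the full complement of planted single-copy marker genes;
the marker for family f descends from a fixed per-family ancestor, mutated
per species (strongly, so species do not share near-identical markers) and
per strain (lightly, so strains of one species do).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import io as gio
from .model import Read, ReferenceGenome

DEFAULT_MARKER_COUNT = 40
DEFAULT_MARKER_LENGTH = 600
ANCESTOR_SEED = 20_240_601  # fixed: marker ancestors are global constants

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass
class CommunityTruth:
    genomes: List[ReferenceGenome]
    sample_strains: Dict[str, str]  # genome_id -> true sampled sequence
    abundances: Dict[str, float]  # over present genomes, sums to 1
    read_origins: Dict[str, Tuple[str, int, str]]  # read_id -> (genome, pos, strand)
    planted_variants: Dict[str, List[Tuple[int, str, str]]]  # vs. the reference
    decoy_ids: List[str] = field(default_factory=list)
    seed: int = 0

    def genome(self, genome_id: str) -> ReferenceGenome:
        return next(g for g in self.genomes if g.genome_id == genome_id)

    @property
    def present_ids(self) -> List[str]:
        return sorted(self.abundances)


def _random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def marker_ancestor(family: int, length: int = DEFAULT_MARKER_LENGTH) -> str:
    """Fixed ancestral sequence of a marker family (pure function of family)."""
    rng = np.random.default_rng([ANCESTOR_SEED, family])
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> Tuple[str, List[Tuple[int, str, str]]]:
    """i.i.d. substitutions to a *different* base; returns (mutant, variants)."""
    if rate <= 0:
        return seq, []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    variants = []
    for pos in hit:
        old = chr(arr[pos])
        if old not in _IDX:
            continue
        new = "ACGT"[(_IDX[old] + int(rng.integers(1, 4))) % 4]
        arr[pos] = ord(new)
        variants.append((int(pos), old, new))
    return arr.tobytes().decode("ascii"), variants


def generate_genome(
    length: int,
    gc: float = 0.5,
    marker_count: int = DEFAULT_MARKER_COUNT,
    marker_length: int = DEFAULT_MARKER_LENGTH,
    seed: int = 0,
    genome_id: str = "genome",
    marker_divergence: float = 0.15,
) -> ReferenceGenome:
    """Random genome with marker_count disjoint planted marker genes.

    The family-f marker is the fixed ancestor of f mutated at
    ``marker_divergence``, placed at a seeded position inside the f-th of
    marker_count equal-width blocks, so intervals never overlap.
    """
    if marker_count * marker_length > length // 2:
        raise ValueError(
            f"cannot place {marker_count} markers of {marker_length} bp in "
            f"{length} bp (would exceed half the genome)"
        )
    rng = np.random.default_rng(seed)
    seq = list(_random_sequence(rng, length, gc))
    block = length // marker_count
    markers: Dict[int, Tuple[int, int]] = {}
    for family in range(1, marker_count + 1):
        ancestor = marker_ancestor(family, marker_length)
        marker, _ = _substitute(ancestor, marker_divergence, rng)
        lo = (family - 1) * block
        offset = int(rng.integers(0, block - marker_length + 1))
        start = lo + offset
        seq[start : start + marker_length] = marker
        markers[family] = (start, start + marker_length)
    return ReferenceGenome(genome_id, "".join(seq), markers)


def mutate_genome(
    base: ReferenceGenome,
    subst_rate: float,
    indel_rate: float = 0.0,
    seed: int = 0,
    derived_id: str = None,
    marker_subst_rate: float = None,
) -> Tuple[ReferenceGenome, List[Tuple[int, str, str]]]:
    """Derived sequence with i.i.d. substitutions and short (1-5 bp) indels.

    ``marker_subst_rate`` lets marker intervals mutate at a different
    (usually lower, conservation-mimicking) rate; it only applies when the
    mutant carries no indels, so the annotation intervals remain valid.
    Variants are reported against the base sequence: substitutions as
    (pos, ref, alt); deletions as (pos, deleted, ""); insertions as
    (pos, "", inserted).
    """
    if not (0 <= subst_rate <= 0.2 and 0 <= indel_rate <= 0.2):
        raise ValueError("rates must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    seq, variants = _substitute(base.sequence, subst_rate, rng)

    if marker_subst_rate is not None and indel_rate == 0:
        # re-impose the base marker sequence, then lightly mutate it
        chars = list(seq)
        kept = [v for v in variants]
        for family in sorted(base.markers):
            s, e = base.markers[family]
            kept = [v for v in kept if not (s <= v[0] < e)]
            sub_rng = np.random.default_rng([seed, family])
            marker, mvars = _substitute(base.sequence[s:e], marker_subst_rate, sub_rng)
            chars[s:e] = marker
            kept.extend((s + p, r, a) for p, r, a in mvars)
        seq = "".join(chars)
        variants = sorted(kept)

    markers = dict(base.markers)
    if indel_rate > 0:
        out = []
        indel_vars = []
        i = 0
        n = len(seq)
        positions = np.nonzero(rng.random(n) < indel_rate)[0]
        pos_set = set(int(p) for p in positions)
        while i < n:
            if i in pos_set:
                size = min(int(rng.geometric(0.5)), 5)
                if rng.random() < 0.5 and i + size <= n:  # deletion
                    indel_vars.append((i, seq[i : i + size], ""))
                    i += size
                    continue
                ins = _random_sequence(rng, size)
                indel_vars.append((i, "", ins))
                out.append(ins)
            out.append(seq[i])
            i += 1
        seq = "".join(out)
        variants = sorted(variants + indel_vars)
        markers = {}  # intervals no longer valid after indels

    derived_id = derived_id or f"{base.genome_id}_mut"
    return ReferenceGenome(derived_id, seq, markers), variants


def make_community(
    seed: int = 0,
    n_species: int = 4,
    species_length: int = 120_000,
    strain_species: int = 1,
    n_strains: int = 3,
    strain_divergence: float = 0.01,
    sample_divergence: float = 0.0,
    sample_indel_rate: float = 0.0,
    n_decoys: int = 2,
    marker_count: int = DEFAULT_MARKER_COUNT,
    marker_length: int = DEFAULT_MARKER_LENGTH,
    abundance_decay: float = 0.3,  # log10 step between adjacent ranks
) -> CommunityTruth:
    """Default desk-scale community.

    ``n_species`` unrelated species genomes; species number ``strain_species``
    additionally contributes ``n_strains - 1`` extra strain references (only
    the first strain is present in the sample).  ``n_decoys`` further
    unrelated genomes go into the reference collection but shed no reads.
    Abundances decay log-linearly over present genomes.
    """
    rng = np.random.default_rng([seed, 0xC0])
    genomes: List[ReferenceGenome] = []
    present: List[str] = []
    variants: Dict[str, List[Tuple[int, str, str]]] = {}

    for s in range(1, n_species + 1):
        gid = f"sp{s}"
        base = generate_genome(
            species_length,
            gc=0.5,
            marker_count=marker_count,
            marker_length=marker_length,
            seed=int(rng.integers(0, 2**31)),
            genome_id=gid,
        )
        if s == strain_species and n_strains > 1:
            for t in range(1, n_strains + 1):
                sid = f"sp{s}s{t}"
                if t == 1:
                    strain = ReferenceGenome(sid, base.sequence, base.markers)
                    svars: List[Tuple[int, str, str]] = []
                else:
                    strain, svars = mutate_genome(
                        base,
                        subst_rate=strain_divergence * (t - 1) / (n_strains - 1),
                        indel_rate=0.0,
                        seed=int(rng.integers(0, 2**31)),
                        derived_id=sid,
                        marker_subst_rate=0.002,
                    )
                genomes.append(strain)
                variants[sid] = svars
            present.append(f"sp{s}s1")
        else:
            genomes.append(base)
            variants[gid] = []
            present.append(gid)

    decoys = []
    for d in range(1, n_decoys + 1):
        gid = f"decoy{d}"
        decoys.append(gid)
        genomes.append(
            generate_genome(
                species_length,
                gc=0.5,
                marker_count=marker_count,
                marker_length=marker_length,
                seed=int(rng.integers(0, 2**31)),
                genome_id=gid,
            )
        )
        variants[gid] = []

    sample_strains: Dict[str, str] = {}
    for gid in present:
        ref = next(g for g in genomes if g.genome_id == gid)
        if sample_divergence > 0 or sample_indel_rate > 0:
            mutant, mvars = mutate_genome(
                ref,
                subst_rate=sample_divergence,
                indel_rate=sample_indel_rate,
                seed=int(rng.integers(0, 2**31)),
                derived_id=f"{gid}_sample",
            )
            sample_strains[gid] = mutant.sequence
            variants[gid] = mvars
        else:
            sample_strains[gid] = ref.sequence

    weights = np.array([10 ** (-abundance_decay * i) for i in range(len(present))])
    weights = weights / weights.sum()
    abundances = {gid: float(w) for gid, w in zip(present, weights)}

    return CommunityTruth(
        genomes=genomes,
        sample_strains=sample_strains,
        abundances=abundances,
        read_origins={},
        planted_variants=variants,
        decoy_ids=decoys,
        seed=seed,
    )


def simulate_reads(
    truth: CommunityTruth,
    read_length: int = 100,
    total_pairs: int = 10_000,
    error_rate: float = 0.0,
    paired: bool = True,
    insert_mean: int = 300,
    insert_sd: int = 30,
    seed: int = 0,
) -> List[Read]:
    """Uniform-position, abundance-weighted reads with substitution errors.

    Populates ``truth.read_origins`` (read_id -> (genome_id, 0-based position
    of the fragment start on the sample strain, strand of mate 1)).  Read
    names carry no truth.  For paired mode each fragment yields mates /1
    (forward) and /2 (reverse complement of the fragment end).
    """
    rng = np.random.default_rng([truth.seed, seed, 0x5EAD])
    ids = truth.present_ids
    probs = np.array([truth.abundances[g] for g in ids])
    picks = rng.choice(len(ids), size=total_pairs, p=probs)
    reads: List[Read] = []
    truth.read_origins = {}
    for i, gi in enumerate(picks):
        gid = ids[int(gi)]
        template = truth.sample_strains[gid]
        n = len(template)
        if paired:
            insert = max(2 * read_length, int(round(rng.normal(insert_mean, insert_sd))))
            insert = min(insert, n)
            start = int(rng.integers(0, n - insert + 1))
            frag = template[start : start + insert]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = _revcomp(frag)
            r1 = frag[:read_length]
            r2 = _revcomp(frag[-read_length:])
            rid = f"r{i:07d}"
            truth.read_origins[f"{rid}/1"] = (gid, start, strand)
            truth.read_origins[f"{rid}/2"] = (gid, start, strand)
            reads.append(Read(f"{rid}/1", _seq_errors(r1, error_rate, rng), mate=1))
            reads.append(Read(f"{rid}/2", _seq_errors(r2, error_rate, rng), mate=2))
        else:
            if n < read_length:
                raise ValueError("read_length exceeds shortest sample strain")
            start = int(rng.integers(0, n - read_length + 1))
            frag = template[start : start + read_length]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                frag = _revcomp(frag)
            rid = f"r{i:07d}"
            truth.read_origins[rid] = (gid, start, strand)
            reads.append(Read(rid, _seq_errors(frag, error_rate, rng)))
    return reads


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _seq_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    mutated, _ = _substitute(seq, rate, rng)
    return mutated


# ---------------------------------------------------------------------------
# on-disk emission (all plain text)


def write_community(truth: CommunityTruth, reads: Sequence[Read], outdir) -> Dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genomes": outdir / "genomes.fasta",
        "markers": outdir / "markers.tsv",
        "reads": outdir / "reads.fastq",
        "truth": outdir / "truth.tsv",
    }
    gio.write_fasta(((g.genome_id, g.sequence) for g in truth.genomes), paths["genomes"])
    gio.write_marker_annotations(
        {g.genome_id: g.markers for g in truth.genomes if g.markers}, paths["markers"]
    )
    gio.write_fastq(reads, paths["reads"])
    with open(paths["truth"], "w") as fh:
        fh.write("read_id\tgenome_id\tposition\tstrand\n")
        for rid in sorted(truth.read_origins):
            gid, pos, strand = truth.read_origins[rid]
            fh.write(f"{rid}\t{gid}\t{pos}\t{strand}\n")
    return paths
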