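"""Canonical k-mer sets, bottom-s MinHash sketches, and sketch-based similarity.

This module is the internal replacement for external k-mer tooling: exact
canonical k-mer sets back the cluster-vs-reads intersection counts, bottom-s
sketches back containment screening of references against read pools, and the
MinHash Jaccard of two genomes is transformed into an ANI estimate.

All hash values are 64-bit outputs of a seeded bijective mixer applied to the
2-bit packing of the canonical k-mer, so for a fixed seed the mapping
k-mer -> hash is injective and runs are bit-reproducible across platforms.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np

DEFAULT_HASH_SEED = 0x9E3779B97F4A7C15

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCATGCA")

# byte -> 2-bit code; 255 marks anything that is not A/C/G/T
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[_b + 32] = _i  # lowercase

_CHUNK = 1 << 16


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per-base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """2-bit codes of a sequence; non-ACGT positions get code 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Packed 2-bit codes of the canonical k-mer at every valid position.

    The canonical k-mer is the lexicographic minimum of the window and its
    reverse complement; with the A<C<G<T / 0<1<2<3 code order this equals the
    numeric minimum of the two packings.  Windows containing non-ACGT bases
    are skipped.  Returns a uint64 array, one entry per valid position, in
    sequence order (a multiset; call np.unique for the set).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 28:
        raise ValueError("k must be <= 28 to fit a 2-bit packing in 64 bits")
    codes = _encode(seq)
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)

    c64 = codes.astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    bad = np.zeros(m, dtype=bool)
    # k shift-add passes: fwd is the big-endian packing of the window, rev the
    # big-endian packing of its reverse complement
    for j in range(k):
        seg = codes[j : j + m]
        bad |= seg == 255
        fwd = (fwd << np.uint64(2)) | (c64[j : j + m] & np.uint64(3))
    for j in range(k - 1, -1, -1):
        rev = (rev << np.uint64(2)) | (
            (np.uint64(3) - c64[j : j + m]) & np.uint64(3)
        )
    canon = np.minimum(fwd, rev)
    return canon[~bad]


def canonical_kmers(sequence: str, k: int) -> Counter:
    """Multiset of canonical k-mer strings (string-level reference path).

    One entry per window 0..len-k that contains no non-ACGT base; each entry
    is min(window, revcomp(window)).  Used directly for small inputs and as
    the readable counterpart of :func:`canonical_kmer_codes`.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = sequence.upper()
    out: Counter = Counter()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(b not in "ACGT" for b in w):
            continue
        rc = revcomp(w)
        out[min(w, rc)] += 1
    return out


def mix64(values: np.ndarray, seed: int = DEFAULT_HASH_SEED) -> np.ndarray:
    """Seeded 64-bit finalizer (murmur3 fmix64); bijective for a fixed seed."""
    h = np.asarray(values, dtype=np.uint64) ^ np.uint64(seed)
    with np.errstate(over="ignore"):
        h ^= h >> np.uint64(33)
        h *= np.uint64(0xFF51AFD7ED558CCD)
        h ^= h >> np.uint64(33)
        h *= np.uint64(0xC4CEB9FE1A85EC53)
        h ^= h >> np.uint64(33)
    return h


@dataclass(frozen=True)
class KmerSet:
    """Exact set of hashed canonical k-mers of a sequence collection.

    ``hashes`` is a sorted, unique uint64 array — set semantics with
    numpy-speed intersections.
    """

    k: int
    hashes: np.ndarray
    source_id: str = ""
    seed: int = DEFAULT_HASH_SEED

    def __len__(self) -> int:
        return int(self.hashes.size)

    def intersection_size(self, other: "KmerSet") -> int:
        _check_compatible(self, other)
        return int(np.intersect1d(self.hashes, other.hashes, assume_unique=True).size)


@dataclass(frozen=True)
class Sketch:
    """Bottom-s MinHash sketch: the s smallest hashes of a canonical k-mer set."""

    k: int
    s: int
    hashes: np.ndarray  # sorted ascending, unique, |hashes| = min(s, distinct k-mers)
    source_id: str = ""
    seed: int = DEFAULT_HASH_SEED

    def __len__(self) -> int:
        return int(self.hashes.size)


def _check_compatible(a: Union[KmerSet, Sketch], b: Union[KmerSet, Sketch]) -> None:
    if a.k != b.k:
        raise ValueError(f"k mismatch: {a.k} != {b.k}")
    if a.seed != b.seed:
        raise ValueError("hash seed mismatch")


def build_kmer_set(
    sequences: Iterable[str],
    k: int,
    source_id: str = "",
    seed: int = DEFAULT_HASH_SEED,
) -> KmerSet:
    """Hash the canonical k-mers of every sequence and take the union."""
    seqs = list(sequences)
    if not seqs:
        raise ValueError("sequence list must be nonempty")
    # one pass over an N-joined concatenation; windows straddling a boundary
    # contain the N separator and are dropped automatically
    codes = np.unique(canonical_kmer_codes("N".join(seqs), k))
    hashes = np.sort(mix64(codes, seed)) if codes.size else codes
    return KmerSet(k=k, hashes=hashes, source_id=source_id, seed=seed)


def bottom_sketch(kmer_set: KmerSet, s: int) -> Sketch:
    """The s numerically smallest hashes of the set (all of them if fewer)."""
    if s < 1:
        raise ValueError("sketch size must be >= 1")
    h = kmer_set.hashes
    kept = h[:s] if h.size > s else h  # hashes are stored sorted
    return Sketch(k=kmer_set.k, s=s, hashes=kept.copy(), source_id=kmer_set.source_id, seed=kmer_set.seed)


def merge_sketches(a: Sketch, b: Sketch) -> Sketch:
    """Bottom-s of the union of two sketches (s = min of the two budgets)."""
    _check_compatible(a, b)
    s = min(a.s, b.s)
    merged = np.unique(np.concatenate([a.hashes, b.hashes]))
    return Sketch(k=a.k, s=s, hashes=merged[:s], source_id=f"{a.source_id}+{b.source_id}", seed=a.seed)


def containment(reference_sketch: Sketch, read_kmers: KmerSet) -> float:
    """Fraction of the reference's sketch hashes present in the read k-mer set."""
    _check_compatible(reference_sketch, read_kmers)
    if len(reference_sketch) == 0:
        raise ValueError(
            f"empty sketch for {reference_sketch.source_id!r}: source has no "
            "valid k-mers (all-N or shorter than k)"
        )
    hits = np.isin(reference_sketch.hashes, read_kmers.hashes, assume_unique=True)
    return float(hits.sum() / reference_sketch.hashes.size)


def kmer_intersection_size(cluster_kmers: KmerSet, unassigned_read_kmers: KmerSet) -> int:
    """Exact size of the intersection of two full k-mer sets (never sketched)."""
    return cluster_kmers.intersection_size(unassigned_read_kmers)


def sketch_jaccard(a: Sketch, b: Sketch) -> float:
    """MinHash Jaccard estimate on the merged bottom-s sketch."""
    _check_compatible(a, b)
    s = min(a.s, b.s)
    merged = np.unique(np.concatenate([a.hashes, b.hashes]))[:s]
    if merged.size == 0:
        return 0.0
    in_a = np.isin(merged, a.hashes, assume_unique=True)
    in_b = np.isin(merged, b.hashes, assume_unique=True)
    return float((in_a & in_b).sum() / merged.size)


def ani_from_jaccard(j: float, k: int) -> Optional[float]:
    """Mash-distance transform: ANI = 100 * (1 + (1/k) * ln(2J / (1 + J))).

    Returns None ("undetected") for J = 0.
    """
    if j <= 0.0:
        return None
    if j >= 1.0:
        return 100.0
    return float(100.0 * (1.0 + (1.0 / k) * np.log(2.0 * j / (1.0 + j))))


def estimate_ani(
    sketch_a: Sketch,
    sketch_b: Sketch,
) -> Optional[float]:
    """Sketch-based ANI estimate in [0, 100]; None when no k-mers are shared.

    Symmetric by construction (Jaccard on the merged sketch).
    """
    return ani_from_jaccard(sketch_jaccard(sketch_a, sketch_b), sketch_a.k)


# ---------------------------------------------------------------------------
# serialization

_SKETCH_FORMAT_VERSION = 1


def write_sketch(sketch: Sketch, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"#guideasm-sketch\tv{_SKETCH_FORMAT_VERSION}\tk={sketch.k}\t"
            f"s={sketch.s}\tseed={sketch.seed}\tsource={sketch.source_id}\n"
        )
        for h in sketch.hashes:
            fh.write(f"{int(h)}\n")


def read_sketch(path) -> Sketch:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#guideasm-sketch"):
            raise ValueError(f"{path}: not a sketch file")
        fields = dict(f.split("=", 1) for f in header.split("\t")[2:])
        hashes = np.array([int(line) for line in fh if line.strip()], dtype=np.uint64)
    return Sketch(
        k=int(fields["k"]),
        s=int(fields["s"]),
        hashes=np.sort(hashes),
        source_id=fields.get("source", ""),
        seed=int(fields["seed"]),
    )
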