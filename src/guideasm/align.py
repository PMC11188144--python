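"""Deterministic desk-scale short-read alignment and coverage tracks.

Seed-and-extend against an exact-seed index: every read position contributes a
seed, each seed hit proposes a full-length ungapped placement, and the
best-identity placement per (read, target) is reported iff identity clears the
threshold.  No gaps in the core aligner — indels between sample and reference
are recovered downstream by the polisher's split-anchored pileup.

The implementation is batched: all reads (both strands) are concatenated, seed
values are packed into uint64 and located in the target's sorted seed array
with searchsorted, and candidates are scored with vectorized base comparison.
Results are identical to aligning each read independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .model import Read
from .sketch import _encode

DEFAULT_MIN_IDENTITY = 0.85
DEFAULT_SEED_LENGTH = 21

# seeds occurring more often than this in the index are skipped (repeat mask)
MAX_SEED_HITS = 200


@dataclass(frozen=True)
class ReadAlignment:
    """Ungapped placement of a read on a target.

    ``start``/``end`` are 0-based half-open target coordinates; ``edits`` are
    (target_position, read_base) pairs for every mismatching column, with the
    read base given in target orientation.
    """

    read_id: str
    target_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    matches: int
    aligned_length: int
    edits: Tuple[Tuple[int, str], ...] = ()

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_length


@dataclass
class CoverageTrack:
    target_id: str
    depth: np.ndarray  # int array, len = target length


def _pack_windows(codes: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """(values, positions) of every length-k window free of non-ACGT bases.

    Big-endian 2-bit packing built with k shift-add passes over the array —
    no (n, k) window matrix is materialized.
    """
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    c64 = codes.astype(np.uint64)
    vals = np.zeros(m, dtype=np.uint64)
    bad = np.zeros(m, dtype=bool)
    for j in range(k):
        seg = codes[j : j + m]
        bad |= seg == 255
        vals = (vals << np.uint64(2)) | (c64[j : j + m] & np.uint64(3))
    pos = np.nonzero(~bad)[0]
    return vals[pos], pos


class TargetIndex:
    """Exact-seed index over one or more target sequences."""

    def __init__(self, targets: Dict[str, str], seed_length: int = DEFAULT_SEED_LENGTH):
        if seed_length < 1 or seed_length > 28:
            raise ValueError("seed_length must be in [1, 28]")
        self.seed_length = seed_length
        self.target_ids: List[str] = sorted(targets)
        self.sequences: Dict[str, str] = {t: targets[t].upper() for t in self.target_ids}

        code_parts, offsets = [], []
        pos = 0
        for tid in self.target_ids:
            offsets.append(pos)
            c = _encode(self.sequences[tid])
            code_parts.append(c)
            code_parts.append(np.full(1, 255, dtype=np.uint8))  # separator
            pos += c.size + 1
        self.codes = (
            np.concatenate(code_parts) if code_parts else np.empty(0, dtype=np.uint8)
        )
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.lengths = np.asarray(
            [len(self.sequences[t]) for t in self.target_ids], dtype=np.int64
        )

        vals, positions = _pack_windows(self.codes, seed_length)
        order = np.argsort(vals, kind="stable")
        self._seed_vals = vals[order]
        self._seed_pos = positions[order]

    def locate(self, query_vals: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """For each query seed value return (expanded query index, target pos).

        Seeds with more than MAX_SEED_HITS occurrences are dropped.
        """
        lo = np.searchsorted(self._seed_vals, query_vals, side="left")
        hi = np.searchsorted(self._seed_vals, query_vals, side="right")
        counts = hi - lo
        keep = counts <= MAX_SEED_HITS
        lo, counts = lo[keep], counts[keep]
        qidx = np.nonzero(keep)[0]
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        # expand [lo, lo+count) ranges
        rep_q = np.repeat(qidx, counts)
        starts = np.repeat(lo, counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        return rep_q, self._seed_pos[starts + within]


def map_reads(
    reads: Sequence[Read],
    targets: Dict[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    seed_length: int = DEFAULT_SEED_LENGTH,
    index: TargetIndex = None,
) -> List[ReadAlignment]:
    """Align reads to targets; at most one (best) alignment per read per target.

    Both the read and its reverse complement are tried.  Ties are broken by
    leftmost target coordinate, then by + strand.  Reads shorter than
    seed_length, or without a placement of identity >= min_identity, are
    simply absent from the output.
    """
    if index is None:
        index = TargetIndex(targets, seed_length)
    if not reads:
        return []

    # concatenate oriented read codes: for each read, fwd then rc
    parts, read_meta = [], []  # meta: (read_idx, strand)
    offsets = []
    pos = 0
    sep = np.full(1, 255, dtype=np.uint8)
    for i, r in enumerate(reads):
        c = _encode(r.sequence)
        rc = (np.uint8(3) - c[::-1]) % np.uint8(255)
        rc[c[::-1] == 255] = 255
        for arr, strand in ((c, "+"), (rc, "-")):
            offsets.append(pos)
            read_meta.append((i, strand))
            parts.append(arr)
            parts.append(sep)
            pos += arr.size + 1
    codes = np.concatenate(parts)
    offsets_arr = np.asarray(offsets, dtype=np.int64)

    k = index.seed_length
    qvals, qpos = _pack_windows(codes, k)
    rep_q, tpos = index.locate(qvals)
    if rep_q.size == 0:
        return []

    gpos = qpos[rep_q]  # global position of the seed within the read concat
    seg = np.searchsorted(offsets_arr, gpos, side="right") - 1
    off_in_read = gpos - offsets_arr[seg]
    cand_start = tpos - off_in_read  # global target coordinate of placement

    # deduplicate (oriented-read segment, target start)
    key = np.stack([seg, cand_start], axis=1)
    key = np.unique(key, axis=0)

    read_lengths = np.asarray([len(r.sequence) for r in reads], dtype=np.int64)

    # candidate must fall entirely within one target
    seg_u, cand_u = key[:, 0], key[:, 1]
    rlen = read_lengths[seg_u // 2]
    t_idx = np.searchsorted(index.offsets, cand_u, side="right") - 1
    ok = (
        (cand_u >= 0)
        & (t_idx >= 0)
        & (cand_u >= index.offsets[t_idx])
        & (cand_u + rlen <= index.offsets[t_idx] + index.lengths[t_idx])
    )
    seg_u, cand_u, t_idx, rlen = seg_u[ok], cand_u[ok], t_idx[ok], rlen[ok]

    # score candidates; keep the best per (read, target)
    # best[(read_idx, target_idx)] = (-matches, start_local, strand_rank, seg)
    best: Dict[Tuple[int, int], Tuple[int, int, int, int]] = {}
    tcodes = index.codes
    for j in range(seg_u.size):
        s = int(seg_u[j])
        cs = int(cand_u[j])
        L = int(rlen[j])
        rcod = codes[offsets_arr[s] : offsets_arr[s] + L]
        eq = rcod == tcodes[cs : cs + L]
        matches = int(eq.sum())
        if matches / L < min_identity:
            continue
        ridx, strand = read_meta[s]
        ti = int(t_idx[j])
        local = cs - int(index.offsets[ti])
        entry = (-matches, local, 0 if strand == "+" else 1, s)
        prev = best.get((ridx, ti))
        if prev is None or entry < prev:
            best[(ridx, ti)] = entry

    out: List[ReadAlignment] = []
    for (ridx, ti) in sorted(best):
        neg_m, local, strand_rank, s = best[(ridx, ti)]
        matches = -neg_m
        r = reads[ridx]
        L = len(r.sequence)
        strand = "+" if strand_rank == 0 else "-"
        tid = index.target_ids[ti]
        gstart = int(index.offsets[ti]) + local
        rcod = codes[offsets_arr[s] : offsets_arr[s] + L]
        neq = np.nonzero(rcod != tcodes[gstart : gstart + L])[0]
        oriented = r.sequence if strand == "+" else _revcomp_str(r.sequence)
        edits = tuple((local + int(p), oriented[int(p)]) for p in neq)
        out.append(
            ReadAlignment(
                read_id=r.read_id,
                target_id=tid,
                start=local,
                end=local + L,
                strand=strand,
                matches=matches,
                aligned_length=L,
                edits=edits,
            )
        )
    return out


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp_str(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def coverage_track(
    alignments: Iterable[ReadAlignment], target_length: int, target_id: str = ""
) -> CoverageTrack:
    """Per-base depth from a set of placements (diff-array accumulation)."""
    diff = np.zeros(target_length + 1, dtype=np.int64)
    for a in alignments:
        if a.start < 0 or a.end > target_length:
            raise ValueError(
                f"alignment [{a.start}, {a.end}) outside target of length {target_length}"
            )
        diff[a.start] += 1
        diff[a.end] -= 1
        if not target_id:
            target_id = a.target_id
    return CoverageTrack(target_id=target_id, depth=np.cumsum(diff[:-1]))


def breadth(track: CoverageTrack, interval: Tuple[int, int]) -> float:
    """Fraction of positions in [start, end) with depth >= 1."""
    start, end = interval
    if end <= start:
        raise ValueError(f"empty interval [{start}, {end})")
    if start < 0 or end > track.depth.size:
        raise ValueError(f"interval [{start}, {end}) outside track")
    window = track.depth[start:end]
    return float((window >= 1).sum() / window.size)


def covered_runs(track: CoverageTrack) -> List[Tuple[int, int]]:
    """Maximal runs of positions with depth >= 1, as half-open intervals."""
    covered = track.depth >= 1
    if not covered.any():
        return []
    padded = np.concatenate([[False], covered, [False]])
    changes = np.nonzero(padded[1:] != padded[:-1])[0]
    return [(int(changes[i]), int(changes[i + 1])) for i in range(0, changes.size, 2)]
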