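"""Pileup-based consensus polishing of assembled contigs.

Supporting reads are realigned to each contig with the internal aligner.  A
read that aligns ungapped contributes its bases column by column; a read
whose ungapped placement is poor (or absent) is split-anchored — its two
halves are aligned independently and a consistent offset between them yields
a single indel of bounded size, with the breakpoint refined to the
match-maximizing split.  The consensus then replaces the contig symbol at
every position where an alternative (base, deletion, or insertion) has
sufficient depth and majority support, and a change report records every
applied edit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import map_reads
from .model import Read
from .sketch import _encode

DEFAULT_MIN_DEPTH = 2
DEFAULT_MAJORITY = 0.6
DEFAULT_MAX_INDEL = 10

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_DEL = 4  # fifth count column

_RC = str.maketrans("ACGTN", "TGCAN")


@dataclass
class Pileup:
    """Per-position evidence over a contig.

    ``counts``[i] holds A/C/G/T/deletion tallies at position i; ``insertions``
    maps a position j to a Counter of strings inserted between j-1 and j.
    ``junction_depth``[j] counts reads whose alignment spans that junction.
    """

    contig_id: str
    counts: np.ndarray  # (L, 5) int64
    insertions: Dict[int, Counter] = field(default_factory=dict)
    junction_depth: np.ndarray = None

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class PolishChange:
    position: int  # 0-based on the input contig
    ref: str  # reference symbol ("" for insertion)
    new: str  # replacement base, "-" for deletion, "+SEQ" for insertion
    support: int
    depth: int


@dataclass
class PolishReport:
    contig_id: str
    changes: List[PolishChange]
    unchanged_low_depth: int


@dataclass(frozen=True)
class _Placement:
    """One read's realignment: ungapped core(s) plus at most one indel."""

    start: int  # contig position of the first aligned base
    segments: Tuple[Tuple[int, str], ...]  # (contig_start, read_segment) pairs
    deletion: Optional[Tuple[int, int]] = None  # (contig_start, length)
    insertion: Optional[Tuple[int, str]] = None  # (contig_position, string)
    matches: int = 0


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


ANCHOR_LENGTH = 25  # prefix/suffix anchor for split-indel detection


def _refine_split(oriented: str, s1: int, s2: int, suffix_offset: int,
                  ccodes: np.ndarray, max_indel: int) -> Optional[_Placement]:
    """Given '+'-strand placements of a read's prefix and suffix anchors,
    place a single indel at the match-maximizing breakpoint."""
    L = len(oriented)
    n = ccodes.size
    g = s2 - s1 - suffix_offset  # >0: deletion of g contig bases; <0: insertion
    if g == 0 or abs(g) > max_indel:
        return None
    rcodes = _encode(oriented)
    if g > 0:
        if s1 < 0 or s1 + L + g > n:
            return None
        eq1 = (rcodes == ccodes[s1 : s1 + L]).astype(np.int64)
        eq2 = (rcodes == ccodes[s1 + g : s1 + g + L]).astype(np.int64)
        pre = np.concatenate([[0], np.cumsum(eq1)])  # matches of read[:j] at s1
        suf = np.concatenate([np.cumsum(eq2[::-1])[::-1], [0]])  # read[j:] at s1+j+g
        totals = pre + suf
        j = int(np.argmax(totals))
        return _Placement(
            start=s1,
            segments=((s1, oriented[:j]), (s1 + j + g, oriented[j:])),
            deletion=(s1 + j, g),
            matches=int(totals[j]),
        )
    d = -g
    if s1 < 0 or s1 + L - d > n:
        return None
    eq1 = (rcodes == ccodes[s1 : s1 + L]).astype(np.int64)
    # read[j+d:] aligned at s1+j  <=>  read[i] vs contig[s1+i-d] for i >= j+d
    eq2 = (rcodes[d:] == ccodes[s1 : s1 + L - d]).astype(np.int64)
    pre = np.concatenate([[0], np.cumsum(eq1)])[: L - d + 1]
    suf = np.concatenate([np.cumsum(eq2[::-1])[::-1], [0]])
    totals = pre + suf
    j = int(np.argmax(totals))
    return _Placement(
        start=s1,
        segments=((s1, oriented[:j]), (s1 + j, oriented[j + d :])),
        insertion=(s1 + j, oriented[j : j + d]),
        matches=int(totals[j]),
    )


def realign(reads: Sequence[Read], contig_seq: str, contig_id: str = "contig",
            min_identity: float = 0.85, seed_length: int = 21,
            max_indel: int = DEFAULT_MAX_INDEL) -> List[_Placement]:
    """Best placement per read: ungapped, or split-anchored if that explains
    strictly more matched bases. Reads placing neither way are dropped.

    Alignment is batched: one multi-read pass for the full reads, one for the
    halves of every read whose ungapped placement is imperfect or missing.
    """
    targets = {contig_id: contig_seq}
    full = {a.read_id: a for a in map_reads(reads, targets, min_identity, seed_length)}

    ungapped: Dict[str, _Placement] = {}
    candidates: List[Read] = []
    for read in reads:
        a = full.get(read.read_id)
        if a is not None:
            oriented = read.sequence if a.strand == "+" else _revcomp(read.sequence)
            ungapped[read.read_id] = _Placement(
                start=a.start, segments=((a.start, oriented),), matches=a.matches
            )
        anchor = max(ANCHOR_LENGTH, seed_length)
        if a is None or a.matches < a.aligned_length - 2:
            if len(read.sequence) >= 2 * anchor:
                candidates.append(read)

    splits: Dict[str, _Placement] = {}
    if candidates:
        anchor = max(ANCHOR_LENGTH, seed_length)
        probes: List[Read] = []
        for i, read in enumerate(candidates):
            fwd = read.sequence
            rev = _revcomp(read.sequence)
            probes.append(Read(f"{i}|F|1", fwd[:anchor]))
            probes.append(Read(f"{i}|F|2", fwd[-anchor:]))
            probes.append(Read(f"{i}|R|1", rev[:anchor]))
            probes.append(Read(f"{i}|R|2", rev[-anchor:]))
        probe_hits = {
            a.read_id: a
            for a in map_reads(probes, targets, min_identity, seed_length)
        }
        ccodes = _encode(contig_seq)
        for i, read in enumerate(candidates):
            best: Optional[_Placement] = None
            for orient_tag in ("F", "R"):
                a1 = probe_hits.get(f"{i}|{orient_tag}|1")
                a2 = probe_hits.get(f"{i}|{orient_tag}|2")
                if a1 is None or a2 is None or a1.strand != "+" or a2.strand != "+":
                    continue
                oriented = (
                    read.sequence if orient_tag == "F" else _revcomp(read.sequence)
                )
                place = _refine_split(
                    oriented, a1.start, a2.start, len(oriented) - anchor,
                    ccodes, max_indel,
                )
                if place and (best is None or place.matches > best.matches):
                    best = place
            if best is not None:
                splits[read.read_id] = best

    out: List[_Placement] = []
    for read in reads:
        cands = [p for p in (ungapped.get(read.read_id), splits.get(read.read_id)) if p]
        if not cands:
            continue
        out.append(max(cands, key=lambda p: p.matches))
    return out


def _soft_clip(seg: str, seg_start: int, contig_seq: str) -> Tuple[int, str]:
    """Trim low-scoring read ends (the max-scoring extent under +1 match /
    -2 mismatch).  A read crossing an indel off-centre aligns ungapped with a
    shifted, ~25%-identity tail; without clipping that tail both dilutes the
    indel column's majority and plants random bases."""
    n = min(len(seg), len(contig_seq) - seg_start)
    if n <= 0:
        return seg_start, ""
    eq = np.frombuffer(seg[:n].encode(), dtype=np.uint8) == np.frombuffer(
        contig_seq[seg_start : seg_start + n].encode(), dtype=np.uint8
    )
    score = np.where(eq, 1, -2)
    prefix = np.concatenate([[0], np.cumsum(score)])
    b = int(np.argmax(prefix))
    a = int(np.argmin(prefix[: b + 1])) if b > 0 else 0
    return seg_start + a, seg[a:b]


def build_pileup(contig_seq: str, placements: Sequence[_Placement],
                 contig_id: str = "contig") -> Pileup:
    L = len(contig_seq)
    counts = np.zeros((L, 5), dtype=np.int64)
    insertions: Dict[int, Counter] = {}
    junction = np.zeros(L + 1, dtype=np.int64)
    for p in placements:
        lo, hi = L, 0
        ungapped = len(p.segments) == 1 and p.deletion is None and p.insertion is None
        for seg_start, seg in p.segments:
            if ungapped:
                seg_start, seg = _soft_clip(seg, seg_start, contig_seq)
            for i, base in enumerate(seg):
                pos = seg_start + i
                if 0 <= pos < L and base in _BASE_IDX:
                    counts[pos, _BASE_IDX[base]] += 1
            if seg:
                lo = min(lo, seg_start)
                hi = max(hi, seg_start + len(seg))
        if p.deletion is not None:
            ds, dl = p.deletion
            for pos in range(ds, min(ds + dl, L)):
                counts[pos, _DEL] += 1
        if p.insertion is not None:
            ipos, iseq = p.insertion
            if 0 <= ipos <= L:
                insertions.setdefault(ipos, Counter())[iseq] += 1
        if hi > lo:
            # a read votes on a junction only when it spans it with >= 3
            # anchored bases either side; soft-clipped tails that extend a
            # base or two by chance must not dilute insertion majorities
            m = 3
            if hi - m + 1 > lo + m:
                junction[lo + m : hi - m + 1] += 1
    return Pileup(contig_id=contig_id, counts=counts, insertions=insertions,
                  junction_depth=junction)


def consensus_polish(contig_seq: str, pileup: Pileup,
                     min_depth: int = DEFAULT_MIN_DEPTH,
                     majority: float = DEFAULT_MAJORITY) -> Tuple[str, PolishReport]:
    """Majority consensus over the pileup.

    At each position with depth >= min_depth, the top symbol (base or
    deletion) replaces the contig base iff its frequency reaches the majority
    threshold AND it outvotes the reference base (exact count ties keep the
    reference).  Insertions are applied at junctions under the same rule
    against the non-inserting spanning reads.
    """
    L = len(contig_seq)
    depth = pileup.depth
    changes: List[PolishChange] = []
    low_depth = 0
    pieces: List[str] = []
    for pos in range(L):
        # insertion between pos-1 and pos
        ins = _call_insertion(pileup, pos, min_depth, majority)
        if ins is not None:
            seq, support, jdepth = ins
            pieces.append(seq)
            changes.append(PolishChange(pos, "", f"+{seq}", support, jdepth))
        ref = contig_seq[pos]
        d = int(depth[pos])
        if d < min_depth:
            pieces.append(ref)
            if d > 0:
                low_depth += 1
            continue
        row = pileup.counts[pos]
        ref_count = int(row[_BASE_IDX[ref]]) if ref in _BASE_IDX else 0
        top = int(np.argmax(row))  # ties -> lower index, deterministic
        top_count = int(row[top])
        symbol = "-" if top == _DEL else _BASES[top]
        if symbol != ref and top_count / d >= majority and top_count > ref_count:
            if symbol == "-":
                changes.append(PolishChange(pos, ref, "-", top_count, d))
                # deleted: emit nothing
            else:
                changes.append(PolishChange(pos, ref, symbol, top_count, d))
                pieces.append(symbol)
        else:
            pieces.append(ref)
    ins = _call_insertion(pileup, L, min_depth, majority)
    if ins is not None:
        seq, support, jdepth = ins
        pieces.append(seq)
        changes.append(PolishChange(L, "", f"+{seq}", support, jdepth))
    report = PolishReport(pileup.contig_id, changes, low_depth)
    return "".join(pieces), report


def _call_insertion(pileup: Pileup, pos: int, min_depth: int, majority: float):
    cands = pileup.insertions.get(pos)
    if not cands:
        return None
    seq, support = max(cands.items(), key=lambda kv: (kv[1], kv[0]))
    # junction_depth already counts inserting reads (their segments span)
    jdepth = int(pileup.junction_depth[pos]) if pileup.junction_depth is not None else support
    jdepth = max(jdepth, support)
    if jdepth < min_depth or support < min_depth:
        return None
    if support / jdepth >= majority and support > jdepth - support:
        return seq, support, jdepth
    return None


def polish_contig(contig_seq: str, reads: Sequence[Read], contig_id: str = "contig",
                  min_identity: float = 0.85, seed_length: int = 21,
                  min_depth: int = DEFAULT_MIN_DEPTH, majority: float = DEFAULT_MAJORITY,
                  max_indel: int = DEFAULT_MAX_INDEL) -> Tuple[str, PolishReport]:
    """Realign -> pileup -> consensus, in one call."""
    placements = realign(reads, contig_seq, contig_id, min_identity, seed_length, max_indel)
    pileup = build_pileup(contig_seq, placements, contig_id)
    return consensus_polish(contig_seq, pileup, min_depth, majority)


def write_change_report(reports: Sequence[PolishReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tposition\tref\tnew\tsupport\tdepth\n")
        for rep in reports:
            for c in rep.changes:
                fh.write(
                    f"{rep.contig_id}\t{c.position}\t{c.ref or '.'}\t{c.new}\t"
                    f"{c.support}\t{c.depth}\n"
                )
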