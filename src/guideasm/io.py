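"""File formats: FASTA, FASTQ (gzip-transparent), marker annotation tables,
AGP v2.1, minimal SAM export, and tabular reports.

FASTA/FASTQ parsing is delegated to Biopython; the AGP and report writers are
small dialect-pinned emitters so outputs are byte-deterministic.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .model import Read, ReferenceGenome

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: PathLike) -> Dict[str, str]:
    """id -> uppercase sequence, multi-record, lowercase tolerated."""
    with _open_text(path) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: PathLike, mate: int = 0) -> List[Read]:
    with _open_text(path) as fh:
        return [
            Read(read_id=title.split()[0], sequence=seq.upper(), quality=qual, mate=mate)
            for title, seq, qual in FastqGeneralIterator(fh)
        ]


def write_fastq(reads: Iterable[Read], path: PathLike) -> None:
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def load_reads(paths: Sequence[PathLike]) -> List[Read]:
    """Load one (single-end) or two (paired) FASTQ files.

    Paired mates keep identical read_ids; accounting treats a pair as used
    if either mate is used, so ids are suffixed with /1 and /2 here to keep
    every record addressable while preserving the pair id as a prefix.
    """
    if len(paths) == 1:
        return read_fastq(paths[0])
    if len(paths) == 2:
        out: List[Read] = []
        for mate, p in enumerate(paths, start=1):
            for r in read_fastq(p, mate=mate):
                rid = r.read_id
                if not rid.endswith(f"/{mate}"):
                    rid = f"{rid}/{mate}"
                out.append(Read(rid, r.sequence, r.quality, mate))
        return out
    raise ValueError("expected one or two FASTQ files")


# ---------------------------------------------------------------------------
# reference genomes + marker annotations


def load_reference_genomes(
    fasta_paths: Sequence[PathLike],
    annotation_path: PathLike = None,
) -> List[ReferenceGenome]:
    """Load genomes (one or more multi-FASTA files) and optional marker table."""
    seqs: Dict[str, str] = {}
    for p in fasta_paths:
        for gid, seq in read_fasta(p).items():
            if gid in seqs:
                raise ValueError(f"duplicate genome id {gid!r}")
            seqs[gid] = seq
    annotations = read_marker_annotations(annotation_path) if annotation_path else {}
    genomes = []
    for gid, seq in seqs.items():
        genomes.append(ReferenceGenome(gid, seq, annotations.get(gid, {})))
    return genomes


def read_marker_annotations(path: PathLike) -> Dict[str, Dict[int, Tuple[int, int]]]:
    """Parse the marker interval table: genome_id -> {family: (start, end)}.

    Native format is tab-separated with header ``genome_id family start end``
    (0-based half-open).  BED is accepted too: chrom/start/end/name with the
    family number in the name column.
    """
    out: Dict[str, Dict[int, Tuple[int, int]]] = {}
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return out
    header = lines[0].split("\t")
    if header[:4] == ["genome_id", "family", "start", "end"]:
        rows = [ln.split("\t") for ln in lines[1:]]
        parsed = [(r[0], int(r[1]), int(r[2]), int(r[3])) for r in rows]
    else:  # BED: chrom start end name
        parsed = []
        for ln in lines:
            f = ln.split("\t")
            parsed.append((f[0], int(f[3]), int(f[1]), int(f[2])))
    for i, (gid, family, start, end) in enumerate(parsed, start=1):
        if end <= start or start < 0:
            raise ValueError(f"{path} row {i}: bad interval [{start}, {end})")
        fam_map = out.setdefault(gid, {})
        if family in fam_map:
            raise ValueError(
                f"{path} row {i}: duplicate marker family {family} for genome {gid!r}"
            )
        fam_map[family] = (start, end)
    return out


def write_marker_annotations(
    annotations: Dict[str, Dict[int, Tuple[int, int]]], path: PathLike
) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tfamily\tstart\tend\n")
        for gid in sorted(annotations):
            for family in sorted(annotations[gid]):
                start, end = annotations[gid][family]
                fh.write(f"{gid}\t{family}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# AGP v2.1


AGP_HEADER = "##agp-version 2.1"


def write_agp(records: Iterable, path: PathLike) -> None:
    """Write AGPRecord rows (see guideasm.assembly) as AGP v2.1."""
    with open(path, "w") as fh:
        fh.write(AGP_HEADER + "\n")
        for rec in records:
            fh.write("\t".join(rec.to_fields()) + "\n")


def read_agp(path: PathLike) -> List[List[str]]:
    rows = []
    with _open_text(path) as fh:
        for ln in fh:
            if ln.startswith("#") or not ln.strip():
                continue
            rows.append(ln.rstrip("\n").split("\t"))
    return rows


# ---------------------------------------------------------------------------
# minimal SAM export (header + mandatory fields, ungapped CIGAR)


def write_sam(alignments: Iterable, targets: Dict[str, str], path: PathLike) -> None:
    """Export ReadAlignments for inspection. Ungapped CIGAR, no quality."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for tid in sorted(targets):
            fh.write(f"@SQ\tSN:{tid}\tLN:{len(targets[tid])}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            fh.write(
                f"{a.read_id}\t{flag}\t{a.target_id}\t{a.start + 1}\t255\t"
                f"{a.aligned_length}M\t*\t0\t0\t*\t*\tNM:i:{a.aligned_length - a.matches}\n"
            )


# ---------------------------------------------------------------------------
# tabular reports


def write_table(rows: List[dict], columns: Sequence[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
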