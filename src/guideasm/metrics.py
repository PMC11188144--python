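"""Assembly evaluation metrics."""

from __future__ import annotations

from typing import Optional, Sequence


def ng25(contig_lengths: Sequence[int], genome_size: int) -> Optional[int]:
    """Largest contig length c such that the summed length of contigs >= c
    exceeds a quarter of the genome size; None when undefined.

    Lengths are scanned longest-first with a running total; the first length
    whose running total exceeds genome_size / 4 is returned.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    quarter = genome_size / 4
    total = 0
    for length in sorted(contig_lengths, reverse=True):
        total += length
        if total > quarter:
            return length
    return None


def fraction_reads_mapped(used: int, total: int) -> float:
    """Reads consumed by assembly over total input reads."""
    if total <= 0:
        raise ValueError("total read count must be positive")
    if not 0 <= used <= total:
        raise ValueError(f"used count {used} outside [0, {total}]")
    return used / total
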