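"""Genomic context of detected arrays: GC content and flanking sequences.

GC content of an array region compared with the genome-wide GC is a simple
screen for horizontally acquired regions; the 2 kb flanks on either side
of an array are extracted for downstream annotation. GC is computed on the
forward strand of the covered interval (member-gene strands are
irrelevant), ambiguous bases (N) are excluded from both numerator and
denominator, and flanks are silently clipped at contig edges, as happens
on draft assemblies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .detector import ArrayUnit

__all__ = ["ArrayContext", "gc_content", "extract_flanks", "array_contexts",
           "context_table"]

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 2000


@dataclass
class ArrayContext:
    array_id: str
    region_seq: str
    left_flank: str
    right_flank: str
    gc_region: Optional[float]
    gc_genome: Optional[float]


def gc_content(seq: str) -> Optional[float]:
    """Fraction (G+C)/(A+C+G+T) of a sequence; N bases are ignored.

    Returns None for an empty or all-N sequence (GC is undefined there);
    any character outside ACGTN is an error.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return None
    return (seq.count("G") + seq.count("C")) / acgt


def extract_flanks(array: ArrayUnit, contig_seq: str,
                   flank_bp: int = DEFAULT_FLANK_BP,
                   gc_genome: Optional[float] = None) -> ArrayContext:
    """Slice the array region and up to ``flank_bp`` of sequence each side.

    1-based inclusive coordinates: left flank covers
    [max(1, begin - flank_bp), begin - 1], right flank
    [end + 1, min(L, end + flank_bp)]. Flanks shorter than ``flank_bp``
    (contig edge) are returned clipped, with a warning logged.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    L = len(contig_seq)
    if array.end > L or array.begin < 1:
        raise ValueError(
            f"array {array.array_id} coordinates exceed contig length {L}"
        )
    region_seq = contig_seq[array.begin - 1:array.end]
    left_start = max(1, array.begin - flank_bp)
    left_flank = contig_seq[left_start - 1:array.begin - 1]
    right_end = min(L, array.end + flank_bp)
    right_flank = contig_seq[array.end:right_end]
    if flank_bp and (len(left_flank) < flank_bp or len(right_flank) < flank_bp):
        logger.warning(
            "array %s: flank truncated at contig edge (left %d bp, right %d bp)",
            array.array_id, len(left_flank), len(right_flank),
        )
    return ArrayContext(
        array_id=array.array_id,
        region_seq=region_seq,
        left_flank=left_flank,
        right_flank=right_flank,
        gc_region=gc_content(region_seq),
        gc_genome=gc_genome,
    )


def array_contexts(arrays: list[ArrayUnit], contig_seqs: dict[str, str],
                   flank_bp: int = DEFAULT_FLANK_BP) -> list[ArrayContext]:
    """Contexts for all arrays of an assembly; genome GC is computed
    N-excluded across all contigs."""
    gc_genome = gc_content("".join(contig_seqs.values())) if contig_seqs else None
    out = []
    for array in arrays:
        if array.contig_id not in contig_seqs:
            raise KeyError(
                f"array {array.array_id}: contig {array.contig_id!r} "
                "missing from the genome FASTA"
            )
        out.append(
            extract_flanks(array, contig_seqs[array.contig_id], flank_bp,
                           gc_genome=gc_genome)
        )
    return out


def _pct(x: Optional[float]) -> str:
    return "" if x is None else f"{100 * x:.1f}"


def context_table(contexts: list[ArrayContext]) -> str:
    """TSV summary: array_id, GC of region and genome (percent, 1 decimal),
    and the realized flank lengths."""
    lines = ["array_id\tgc_region_pct\tgc_genome_pct\tleft_flank_bp\tright_flank_bp"]
    for c in contexts:
        lines.append(
            f"{c.array_id}\t{_pct(c.gc_region)}\t{_pct(c.gc_genome)}\t"
            f"{len(c.left_flank)}\t{len(c.right_flank)}"
        )
    return "\n".join(lines) + "\n"


def context_fasta(contexts: list[ArrayContext]) -> str:
    """FASTA of each array region with its flanks attached, for annotation."""
    out = []
    for c in contexts:
        seq = c.left_flank + c.region_seq + c.right_flank
        out.append(f">{c.array_id} region+{len(c.left_flank)}bp/"
                   f"{len(c.right_flank)}bp flanks")
        for k in range(0, len(seq), 70):
            out.append(seq[k:k + 70])
    return "\n".join(out) + "\n"
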