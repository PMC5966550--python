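"""Expanding-window detection of tRNA array units.

A tRNA array unit is a genomic region with at least ``min_trnas`` tRNA
genes (default 20) at a density of at least ``min_density`` tRNA genes per
kilobase (default 2.0). Detection scans each contig with a window of the
minimum gene count: while the window is below the density threshold it
slides by one gene; once it qualifies it is registered as a partial array
and grown one gene at a time at its right edge, re-registering after every
growth step that stays at or above the threshold. The first growth step
that drops below the threshold (or running out of genes) finalizes the
last registered partial array; the scan then resumes at the gene after the
array. Arrays on one contig are therefore disjoint and reported in
ascending coordinate order.

Span is measured end-to-end over the covered interval:
``span = end(last gene) - start(first gene) + 1`` and
``density = count / (span / 1000)``. Both threshold comparisons are
inclusive. The greedy growth deliberately stops at the first failing
extension with no lookahead, even if a later gene could restore the
density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trna_io import ContigCalls, GeneCall, ReportRow

__all__ = ["DetectorConfig", "ArrayUnit", "span_and_density",
           "detect_arrays", "detect_genome"]


@dataclass(frozen=True)
class DetectorConfig:
    """Detection thresholds.

    min_trnas : minimum number of counted genes in an array (>= 2).
    min_density : minimum density in tRNA genes per kb (> 0).
    count_tmrna : whether tmRNA genes count toward size and density
        (by convention only tRNA genes do; tmRNAs inside the span are
        still reported separately).
    """

    min_trnas: int = 20
    min_density: float = 2.0
    count_tmrna: bool = False

    def __post_init__(self) -> None:
        if self.min_trnas < 2:
            raise ValueError("min_trnas must be >= 2")
        if self.min_density <= 0:
            raise ValueError("min_density must be > 0")


@dataclass
class ArrayUnit:
    """A detected tRNA array unit on one contig."""

    contig_id: str
    contig_index: int
    genes: list[GeneCall]
    begin: int
    end: int
    span: int
    count: int
    density: float
    tmrna_inside: list[GeneCall] = field(default_factory=list)
    ordinal: int = 1

    @property
    def array_id(self) -> str:
        return f"{self.contig_id}:{self.begin}-{self.end}"


def span_and_density(genes: list[GeneCall], i: int, j: int) -> tuple[int, float]:
    """Span (bp) and density (genes/kb) of the window genes[i..j] inclusive.

    ``genes`` must be sorted by start; ``0 <= i <= j < len(genes)``.
    """
    if i > j:
        raise ValueError(f"window indices out of order: i={i} > j={j}")
    if i < 0 or j >= len(genes):
        raise IndexError(f"window [{i},{j}] outside 0..{len(genes) - 1}")
    if any(genes[k].start > genes[k + 1].start for k in range(i, j)):
        raise ValueError("genes must be sorted by start coordinate")
    span = genes[j].end - genes[i].start + 1
    return span, (j - i + 1) / (span / 1000)


def detect_arrays(contig: ContigCalls, cfg: DetectorConfig = DetectorConfig()
                  ) -> list[ArrayUnit]:
    """Run the expanding-window scan on one contig.

    Returns disjoint arrays in ascending begin order, each satisfying the
    configured size and density thresholds. tmRNA genes whose coordinates
    lie fully within an array's span are attached as ``tmrna_inside``.
    """
    if cfg.count_tmrna:
        counted = list(contig.calls)
    else:
        counted = [g for g in contig.calls if g.kind == "tRNA"]
    tmrnas = [g for g in contig.calls if g.kind == "tmRNA"]

    arrays: list[ArrayUnit] = []
    n = len(counted)
    i = 0
    while i + cfg.min_trnas <= n:
        j = i + cfg.min_trnas - 1
        span, density = span_and_density(counted, i, j)
        if density < cfg.min_density:
            i += 1  # slide: advance relative to first and last gene
            continue
        partial = (i, j, span, density)  # registered partial array
        while True:
            j += 1  # grow: advance relative to the last gene only
            if j >= n:
                break
            span, density = span_and_density(counted, i, j)
            if density < cfg.min_density:
                break
            partial = (i, j, span, density)
        pi, pj, pspan, pdensity = partial
        genes = counted[pi:pj + 1]
        begin, end = genes[0].start, genes[-1].end
        arrays.append(
            ArrayUnit(
                contig_id=contig.contig_id,
                contig_index=contig.contig_index,
                genes=genes,
                begin=begin,
                end=end,
                span=pspan,
                count=pj - pi + 1,
                density=pdensity,
                tmrna_inside=[t for t in tmrnas
                              if begin <= t.start and t.end <= end],
                ordinal=len(arrays) + 1,
            )
        )
        i = pj + 1  # resume after the finalized array
    return arrays


def detect_genome(contigs: list[ContigCalls],
                  cfg: DetectorConfig = DetectorConfig(),
                  genome_id: str = "genome") -> list[ReportRow]:
    """Detect arrays across all contigs of one assembly and build the report.

    Ordinals run 1..n across the genome in (contig_index, begin) order.
    ``total_trnas`` counts kind=tRNA genes genome-wide; tmRNAs never count
    toward it. A genome without arrays yields a single row with empty
    array fields.
    """
    seen_idx = set()
    for c in contigs:
        if c.contig_index in seen_idx:
            raise ValueError(f"duplicate contig_index {c.contig_index}")
        seen_idx.add(c.contig_index)

    total_trnas = sum(
        1 for c in contigs for g in c.calls if g.kind == "tRNA"
    )
    all_arrays: list[ArrayUnit] = []
    for contig in sorted(contigs, key=lambda c: c.contig_index):
        all_arrays.extend(detect_arrays(contig, cfg))
    all_arrays.sort(key=lambda a: (a.contig_index, a.begin))

    if not all_arrays:
        return [ReportRow(genome_id, total_trnas)]
    rows = []
    for ordinal, a in enumerate(all_arrays, start=1):
        a.ordinal = ordinal
        rows.append(
            ReportRow(
                genome_id=genome_id,
                total_trnas=total_trnas,
                array_trna_count=a.count,
                array_length=a.span,
                begin=a.begin,
                end=a.end,
                density=a.count / (a.span / 1000),
                contig_number=a.contig_index,
                array_ordinal=ordinal,
            )
        )
    return rows
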