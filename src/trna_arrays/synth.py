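"""Seeded synthetic genomes with planted tRNA arrays.

The generator emulates the shape of real survey inputs — multi-contig
draft assemblies carrying dense tRNA clusters (tens of genes, regular
spacing, a few kb overall, densities of a few genes per kb) against a
background of dispersed housekeeping tRNAs — while staying fully
deterministic: one spec plus one seed always yields byte-identical FASTA
and prediction files. Each contig draws from its own seed-derived
substream, so appending a contig to a spec leaves earlier contigs'
sequences unchanged.

Planted genes get placeholder sequences (random bases of the configured
gene length): detection operates on coordinates, not sequence content, so
sequence-level tRNA realism is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .detector import ArrayUnit
from .trna_io import ISOTYPE_ALPHABET, ISOTYPE_TO_NAME, GeneCall

__all__ = ["PlantedArray", "SyntheticGenomeSpec", "simulate_genome",
           "plant_density", "parse_spec_config", "truth_table"]

STANDARD_ISOTYPES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedArray:
    """Recipe for one planted cluster.

    Genes are laid out at fixed start-to-start ``spacing`` beginning at
    ``start`` (1-based), one gene per isotype letter in order. With
    ``include_tmrna_at=k`` a tmRNA occupies an extra slot inserted at
    index k (the tRNA genes from index k on shift one slot right).
    """

    contig_index: int  # 1-based index into SyntheticGenomeSpec.contigs
    start: int
    isotypes: str
    gene_length: int = 76
    spacing: int = 150
    strand: str = "+"
    include_tmrna_at: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.isotypes:
            raise ValueError("planted array needs at least one isotype")
        bad = set(self.isotypes) - ISOTYPE_ALPHABET
        if bad:
            raise ValueError(f"unknown isotypes {sorted(bad)}")
        if self.spacing <= self.gene_length:
            raise ValueError("spacing must exceed gene_length")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be + or -")
        if self.include_tmrna_at is not None and not (
                0 <= self.include_tmrna_at <= len(self.isotypes)):
            raise ValueError("include_tmrna_at out of range")

    @property
    def n_slots(self) -> int:
        return len(self.isotypes) + (self.include_tmrna_at is not None)

    @property
    def region_end(self) -> int:
        return self.start + (self.n_slots - 1) * self.spacing + self.gene_length - 1


@dataclass
class SyntheticGenomeSpec:
    """Recipe for one synthetic assembly.

    contigs : list of (length bp, GC fraction) pairs.
    planted : planted arrays; regions must be pairwise non-overlapping and
        fit inside their contigs.
    background_trnas : dispersed tRNAs placed uniformly at random outside
        planted regions, at least ``min_gap`` bp away from any planted
        array and at least ``background_min_spacing`` bp start-to-start
        from each other.
    """

    seed: int
    contigs: list[tuple[int, float]]
    planted: list[PlantedArray] = field(default_factory=list)
    background_trnas: int = 0
    min_gap: int = 5000
    background_min_spacing: int = 0
    background_gene_length: int = 76

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("spec needs at least one contig")
        for length, gc in self.contigs:
            if length <= 0 or not 0 <= gc <= 1:
                raise ValueError(f"bad contig recipe ({length}, {gc})")
        per_contig: dict[int, list[PlantedArray]] = {}
        for p in self.planted:
            if not 1 <= p.contig_index <= len(self.contigs):
                raise ValueError(f"planted array on unknown contig {p.contig_index}")
            length = self.contigs[p.contig_index - 1][0]
            if p.start < 1 or p.region_end > length:
                raise ValueError(
                    f"planted array [{p.start},{p.region_end}] does not fit "
                    f"in contig {p.contig_index} ({length} bp)"
                )
            per_contig.setdefault(p.contig_index, []).append(p)
        for idx, arrays in per_contig.items():
            arrays = sorted(arrays, key=lambda p: p.start)
            for a, b in zip(arrays, arrays[1:]):
                if b.start <= a.region_end:
                    raise ValueError(f"planted arrays overlap on contig {idx}")


def plant_density(n_genes: int, spacing: int, gene_length: int) -> float:
    """Closed-form density (genes/kb) of a cluster of ``n_genes`` genes at
    fixed start-to-start ``spacing``: n / (((n-1)*spacing + gene_length)/1000)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes > 1 and spacing <= gene_length:
        raise ValueError("spacing must exceed gene_length")
    span = (n_genes - 1) * spacing + gene_length
    return n_genes / (span / 1000)


def _contig_id(index: int) -> str:
    return f"contig_{index}"


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _apportion(total: int, weights: list[int]) -> list[int]:
    """Largest-remainder apportionment; deterministic."""
    s = sum(weights)
    exact = [total * w / s for w in weights]
    base = [int(e) for e in exact]
    rem = total - sum(base)
    order = sorted(range(len(weights)), key=lambda k: (base[k] - exact[k], k))
    for k in order[:rem]:
        base[k] += 1
    return base


def _planted_genes(p: PlantedArray, contig_id: str,
                   rng: np.random.Generator) -> list[GeneCall]:
    genes = []
    iso_iter = iter(p.isotypes)
    for slot in range(p.n_slots):
        start = p.start + slot * p.spacing
        end = start + p.gene_length - 1
        if p.include_tmrna_at is not None and slot == p.include_tmrna_at:
            genes.append(GeneCall(contig_id, start, end, p.strand,
                                  "tmRNA", "X", "nnn"))
        else:
            iso = next(iso_iter)
            ac = "".join(rng.choice(list("acgt"), size=3)) if iso != "X" else "nnn"
            genes.append(GeneCall(contig_id, start, end, p.strand,
                                  "tRNA", iso, ac))
    return genes


def simulate_genome(spec: SyntheticGenomeSpec
                    ) -> tuple[str, str, list[ArrayUnit]]:
    """Generate (genome FASTA, ARAGORN-dialect predictions, truth arrays).

    Truth arrays are computed directly from the planted coordinates
    (begin/end of the first/last tRNA gene, end-to-end span, count of tRNA
    genes), independently of any detector.
    """
    fasta_parts: list[str] = []
    pred_parts: list[str] = []
    truth: list[ArrayUnit] = []

    planted_by_contig: dict[int, list[PlantedArray]] = {}
    for p in spec.planted:
        planted_by_contig.setdefault(p.contig_index, []).append(p)

    bg_counts = _apportion(
        spec.background_trnas, [length for length, _ in spec.contigs]
    ) if spec.background_trnas else [0] * len(spec.contigs)

    ordinal = 0
    for idx, (length, gc) in enumerate(spec.contigs, start=1):
        rng = np.random.default_rng([spec.seed % (2 ** 31), idx])
        cid = _contig_id(idx)
        seq = _random_bases(rng, length, gc)

        genes: list[GeneCall] = []
        planted = sorted(planted_by_contig.get(idx, []), key=lambda p: p.start)
        forbidden: list[tuple[int, int]] = []  # planted regions +/- min_gap
        for p in planted:
            genes.extend(_planted_genes(p, cid, rng))
            forbidden.append((max(1, p.start - spec.min_gap),
                              min(length, p.region_end + spec.min_gap)))

        # dispersed background tRNAs by rejection sampling
        placed_starts: list[int] = []
        glen = spec.background_gene_length
        for _ in range(bg_counts[idx - 1]):
            for _attempt in range(10000):
                start = int(rng.integers(1, length - glen + 2))
                end = start + glen - 1
                if any(start <= hi and end >= lo for lo, hi in forbidden):
                    continue
                if any(abs(start - s) < max(spec.background_min_spacing, glen)
                       for s in placed_starts):
                    continue
                break
            else:
                raise RuntimeError(
                    f"could not place background tRNA on contig {idx}; "
                    "contig too crowded for the requested gaps"
                )
            placed_starts.append(start)
            iso = str(rng.choice(list(STANDARD_ISOTYPES)))
            strand = str(rng.choice(["+", "-"]))
            ac = "".join(rng.choice(list("acgt"), size=3))
            genes.append(GeneCall(cid, start, end, strand, "tRNA", iso, ac))

        genes.sort(key=GeneCall.sort_key)
        # placeholder gene sequences overwrite the background bases
        for g in genes:
            seq[g.start - 1:g.end] = _random_bases(rng, g.length, 0.5)

        seq_str = b"".join(seq.tolist()).decode()
        fasta_parts.append(f">{cid} synthetic")
        fasta_parts.extend(seq_str[k:k + 70] for k in range(0, length, 70))

        pred_parts.append(f">{cid}")
        for g in genes:
            comp = "c" if g.strand == "-" else ""
            if g.kind == "tmRNA":
                header = f"tmRNA {comp}[{g.start},{g.end}]"
            else:
                name = ISOTYPE_TO_NAME[g.isotype]
                header = f"tRNA-{name}({g.anticodon}) {comp}[{g.start},{g.end}]"
            pred_parts.append(header)
            pred_parts.append(seq_str[g.start - 1:g.end].lower())

        for p in planted:
            ordinal += 1
            pgenes = _planted_genes_cached(genes, p, cid)
            trnas = [g for g in pgenes if g.kind == "tRNA"]
            begin, end = trnas[0].start, trnas[-1].end
            span = end - begin + 1
            truth.append(ArrayUnit(
                contig_id=cid,
                contig_index=idx,
                genes=trnas,
                begin=begin,
                end=end,
                span=span,
                count=len(trnas),
                density=len(trnas) / (span / 1000),
                tmrna_inside=[g for g in pgenes if g.kind == "tmRNA"
                              and begin <= g.start and g.end <= end],
                ordinal=ordinal,
            ))

    return ("\n".join(fasta_parts) + "\n",
            "\n".join(pred_parts) + "\n",
            truth)


def _planted_genes_cached(genes: list[GeneCall], p: PlantedArray,
                          cid: str) -> list[GeneCall]:
    """Select this planted array's genes back out of the contig gene list."""
    return [g for g in genes
            if p.start <= g.start and g.end <= p.region_end]


def truth_table(truth: list[ArrayUnit]) -> str:
    """TSV of the planted ground truth, one line per array."""
    lines = ["contig\tcontig_index\tordinal\tbegin\tend\tspan\tcount\t"
             "density\tisotypes\ttmrna_inside"]
    for a in truth:
        iso = "".join(g.isotype for g in a.genes)
        lines.append(
            f"{a.contig_id}\t{a.contig_index}\t{a.ordinal}\t{a.begin}\t"
            f"{a.end}\t{a.span}\t{a.count}\t{a.density:.4f}\t{iso}\t"
            f"{len(a.tmrna_inside)}"
        )
    return "\n".join(lines) + "\n"


# --- key-value spec files (CLI `simulate`) --------------------------------

def parse_spec_config(text: str) -> SyntheticGenomeSpec:
    """Parse the key-value recipe format for `simulate`.

    Lines (``#`` comments allowed)::

        seed = 7
        contig = 100000 0.65          # length_bp gc_fraction; repeatable
        array = contig=1 start=5000 isotypes=GCLVAD... spacing=150 \
                gene_length=76 strand=+ tmrna_at=3   # repeatable
        background_trnas = 10
        min_gap = 20000
        background_min_spacing = 0
    """
    seed = 0
    contigs: list[tuple[int, float]] = []
    planted: list[PlantedArray] = []
    scalars: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected key = value")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key == "seed":
            seed = int(value)
        elif key == "contig":
            length_s, gc_s = value.split()
            contigs.append((int(length_s), float(gc_s)))
        elif key == "array":
            kv = dict(tok.split("=", 1) for tok in value.split())
            planted.append(PlantedArray(
                contig_index=int(kv["contig"]),
                start=int(kv["start"]),
                isotypes=kv["isotypes"],
                gene_length=int(kv.get("gene_length", 76)),
                spacing=int(kv.get("spacing", 150)),
                strand=kv.get("strand", "+"),
                include_tmrna_at=(int(kv["tmrna_at"])
                                  if "tmrna_at" in kv else None),
            ))
        elif key in ("background_trnas", "min_gap", "background_min_spacing",
                     "background_gene_length"):
            scalars[key] = int(value)
        else:
            raise ValueError(f"line {lineno}: unknown key {key!r}")
    return SyntheticGenomeSpec(seed=seed, contigs=contigs, planted=planted,
                               **scalars)
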