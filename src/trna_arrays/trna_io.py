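"""Readers and writers for tRNA gene predictions and array reports.

Supported inputs:

* the FASTA-like dialect ARAGORN emits with ``-fons`` (contig sentinel
  lines starting ``>``, one feature header per predicted gene, optional
  sequence lines that are ignored for detection);
* GFF3 with ``tRNA``/``tmRNA`` feature types;
* a generic 7-column tab-separated table;
* plain FASTA genome sequences.

The output side writes the tab-delimited array report: one line per
detected array (or one line with empty array fields for a genome without
arrays), densities printed to two decimals, arrays numbered ``#1, #2, …``
within a genome.

Coordinates are 1-based and inclusive throughout, matching ARAGORN's
``[start,end]`` rendering; GFF3 coordinates need no shift.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Optional

from Bio import SeqIO

__all__ = [
    "GeneCall",
    "ContigCalls",
    "ReportRow",
    "ParseError",
    "ISOTYPE_ALPHABET",
    "parse_aragorn_fasta",
    "parse_gff3",
    "parse_generic_table",
    "read_fasta",
    "write_report",
    "parse_report",
    "write_generic_table",
]

#: Single-letter isotype codes: the 20 standard amino acids plus
#: selenocysteine (U), pyrrolysine (O) and undetermined (X).
ISOTYPE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYUOX")

# 3-letter (and a few spelled-out) amino-acid names as printed by tRNA
# prediction software, mapped to single-letter isotypes.
_NAME_TO_ISOTYPE = {
    "Ala": "A", "Cys": "C", "Asp": "D", "Glu": "E", "Phe": "F",
    "Gly": "G", "His": "H", "Ile": "I", "Lys": "K", "Leu": "L",
    "Met": "M", "Asn": "N", "Pro": "P", "Gln": "Q", "Arg": "R",
    "Ser": "S", "Thr": "T", "Val": "V", "Trp": "W", "Tyr": "Y",
    "Sec": "U", "SeC": "U", "Pyl": "O", "???": "X", "Xxx": "X",
}
ISOTYPE_TO_NAME = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
    "U": "Sec", "O": "Pyl", "X": "???",
}


class ParseError(ValueError):
    """Raised when an input file violates its format; carries line numbers."""


@dataclass(frozen=True, order=True)
class GeneCall:
    """One predicted tRNA or tmRNA gene.

    Coordinates are 1-based inclusive on the forward strand; for genes on
    the complementary strand ``start < end`` still holds and the strand is
    recorded separately.
    """

    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str  # "tRNA" or "tmRNA"
    isotype: str  # single letter from ISOTYPE_ALPHABET; tmRNA -> "X"
    anticodon: str  # 3 chars over acgt, or "nnn" when unknown

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene on {self.contig_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.kind not in ("tRNA", "tmRNA"):
            raise ValueError(f"kind must be tRNA or tmRNA, got {self.kind!r}")
        if self.isotype not in ISOTYPE_ALPHABET:
            raise ValueError(f"unknown isotype {self.isotype!r}")
        if self.kind == "tmRNA" and self.isotype != "X":
            raise ValueError("tmRNA genes carry isotype X")
        if not re.fullmatch(r"[acgt]{3}|nnn", self.anticodon):
            raise ValueError(f"bad anticodon {self.anticodon!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def sort_key(self) -> tuple:
        # total order so runs are reproducible even with shared starts
        return (self.start, self.end, self.strand, self.isotype)


@dataclass
class ContigCalls:
    """All gene calls on one contig, sorted by (start, end)."""

    contig_id: str
    contig_index: int  # 1-based order of appearance in the input
    calls: list[GeneCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.calls = sorted(self.calls, key=GeneCall.sort_key)
        seen = set()
        for c in self.calls:
            if c.contig_id != self.contig_id:
                raise ValueError(
                    f"call on {c.contig_id} grouped under {self.contig_id}"
                )
            key = (c.start, c.end, c.strand, c.kind)
            if key in seen:
                raise ValueError(f"duplicate gene call {key} on {self.contig_id}")
            seen.add(key)


@dataclass
class ReportRow:
    """One line of the tab-delimited array report.

    A genome without any array produces a row whose array fields are all
    ``None`` (rendered as empty cells) with only ``genome_id`` and
    ``total_trnas`` filled.
    """

    genome_id: str
    total_trnas: int
    array_trna_count: Optional[int] = None
    array_length: Optional[int] = None
    begin: Optional[int] = None
    end: Optional[int] = None
    density: Optional[float] = None
    contig_number: Optional[int] = None
    array_ordinal: Optional[int] = None

    def __post_init__(self) -> None:
        if self.total_trnas < 0:
            raise ValueError("total_trnas must be non-negative")
        array_fields = (
            self.array_trna_count, self.array_length, self.begin,
            self.end, self.density, self.contig_number, self.array_ordinal,
        )
        if all(f is None for f in array_fields):
            return
        if any(f is None for f in array_fields):
            raise ValueError("array fields must be all present or all absent")
        if self.begin > self.end:
            raise ValueError("begin > end")
        if self.array_length != self.end - self.begin + 1:
            raise ValueError("array_length must equal end - begin + 1")
        expected = self.array_trna_count / (self.array_length / 1000)
        if abs(self.density - expected) > 1e-9:
            raise ValueError(
                f"density {self.density} inconsistent with "
                f"{self.array_trna_count} genes over {self.array_length} bp"
            )

    @property
    def has_array(self) -> bool:
        return self.array_trna_count is not None


# --- ARAGORN dialect ---------------------------------------------------

_FEATURE_RE = re.compile(
    r"^(?:>?\s*(?:\d+-\d+\s+)?)?"  # optional per-gene fasta prefix
    r"(?P<feat>tRNA-(?P<name>[A-Za-z?]{3,})(?:\((?P<ac>[a-z]{3})\))?|tmRNA)"
    r"\s+(?P<comp>c?)\[(?P<start>\d+),(?P<end>\d+)\]"
)
_SEQ_RE = re.compile(r"^[acgtunACGTUN]+$")


def parse_aragorn_fasta(text: str) -> list[ContigCalls]:
    """Parse the ARAGORN ``-fons`` FASTA dialect into per-contig gene calls.

    Contig sentinel lines start with ``>``; feature headers look like
    ``tRNA-Phe(gaa) [1000,1075]`` or ``tmRNA c[500,850]`` where a leading
    ``c`` before the coordinate block marks the complementary strand.
    Sequence lines are ignored.
    """
    contigs: dict[str, ContigCalls] = {}
    pending: dict[str, list[GeneCall]] = {}
    current: Optional[str] = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _FEATURE_RE.match(line)
        if line.startswith(">") and m is None:
            current = line[1:].split()[0] if line[1:].split() else ""
            if not current:
                raise ParseError(f"line {lineno}: contig sentinel without identifier")
            if current not in contigs:
                contigs[current] = ContigCalls(current, len(contigs) + 1)
                pending[current] = []
            continue
        if m is not None:
            if current is None:
                raise ParseError(f"line {lineno}: feature before any contig sentinel")
            feat = m.group("feat")
            start, end = int(m.group("start")), int(m.group("end"))
            if end < start:
                raise ParseError(f"line {lineno}: end {end} < start {start}")
            strand = "-" if m.group("comp") == "c" else "+"
            if feat == "tmRNA":
                kind, isotype, anticodon = "tmRNA", "X", "nnn"
            else:
                kind = "tRNA"
                name = m.group("name")
                isotype = _NAME_TO_ISOTYPE.get(name)
                if isotype is None:
                    isotype = "X" if set(name) <= {"?"} else None
                if isotype is None:
                    raise ParseError(f"line {lineno}: unknown tRNA isotype {name!r}")
                anticodon = m.group("ac") or "nnn"
            try:
                call = GeneCall(current, start, end, strand, kind, isotype, anticodon)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            pending[current].append(call)
            continue
        if _SEQ_RE.match(line):
            continue  # gene sequence line
        if line.lower().startswith(("trna", "tmrna")) or "[" in line:
            raise ParseError(f"line {lineno}: malformed feature header: {raw!r}")
        raise ParseError(f"line {lineno}: unrecognized line: {raw!r}")
    return [
        ContigCalls(cid, cc.contig_index, pending[cid])
        for cid, cc in contigs.items()
    ]


# --- GFF3 ---------------------------------------------------------------

def parse_gff3(text: str) -> list[ContigCalls]:
    """Parse GFF3, keeping only tRNA and tmRNA features.

    The isotype is taken from a ``product`` (e.g. ``tRNA-Gly``) or
    ``isotype`` attribute when present, else recorded as undetermined (X).
    """
    from gffutils.feature import feature_from_line

    contigs: dict[str, ContigCalls] = {}
    pending: dict[str, list[GeneCall]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        try:
            feat = feature_from_line(line)
        except Exception as exc:
            raise ParseError(f"line {lineno}: not a valid GFF3 line ({exc})") from exc
        if feat.featuretype not in ("tRNA", "tmRNA"):
            continue
        try:
            start, end = int(feat.start), int(feat.end)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"line {lineno}: non-integer coordinates") from exc
        if start > end:
            raise ParseError(f"line {lineno}: start {start} > end {end}")
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        if feat.featuretype == "tmRNA":
            kind, isotype, anticodon = "tmRNA", "X", "nnn"
        else:
            kind = "tRNA"
            isotype = _isotype_from_attributes(feat.attributes)
            anticodon = _anticodon_from_attributes(feat.attributes)
        cid = feat.seqid
        if cid not in contigs:
            contigs[cid] = ContigCalls(cid, len(contigs) + 1)
            pending[cid] = []
        try:
            pending[cid].append(
                GeneCall(cid, start, end, strand, kind, isotype, anticodon)
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return [
        ContigCalls(cid, cc.contig_index, pending[cid])
        for cid, cc in contigs.items()
    ]


def _isotype_from_attributes(attributes) -> str:
    for key in ("isotype", "product", "Name", "name"):
        for value in attributes.get(key, []):
            m = re.search(r"tRNA-([A-Za-z?]{3,})", value)
            token = m.group(1) if m else value
            if token in _NAME_TO_ISOTYPE:
                return _NAME_TO_ISOTYPE[token]
            if len(token) == 1 and token.upper() in ISOTYPE_ALPHABET:
                return token.upper()
    return "X"


def _anticodon_from_attributes(attributes) -> str:
    for value in attributes.get("anticodon", []):
        if re.fullmatch(r"[acgtACGT]{3}", value):
            return value.lower()
    return "nnn"


# --- generic table ------------------------------------------------------

_TABLE_COLUMNS = ("contig", "start", "end", "strand", "kind", "isotype", "anticodon")


def parse_generic_table(text: str) -> list[ContigCalls]:
    """Parse the 7-column TSV: contig, start, end, strand, kind, isotype,
    anticodon. A header line matching the column names is skipped."""
    contigs: dict[str, ContigCalls] = {}
    pending: dict[str, list[GeneCall]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) != len(_TABLE_COLUMNS):
            raise ParseError(
                f"line {lineno}: expected {len(_TABLE_COLUMNS)} tab-separated "
                f"columns, got {len(fields)}"
            )
        if tuple(f.strip().lower() for f in fields) == _TABLE_COLUMNS:
            continue
        cid, start_s, end_s, strand, kind, isotype, anticodon = (
            f.strip() for f in fields
        )
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer coordinates") from exc
        if cid not in contigs:
            contigs[cid] = ContigCalls(cid, len(contigs) + 1)
            pending[cid] = []
        try:
            pending[cid].append(
                GeneCall(cid, start, end, strand, kind, isotype, anticodon)
            )
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
    return [
        ContigCalls(cid, cc.contig_index, pending[cid])
        for cid, cc in contigs.items()
    ]


def write_generic_table(contigs: list[ContigCalls]) -> str:
    """Emit gene calls in the generic-table format (inverse of
    :func:`parse_generic_table`)."""
    lines = ["\t".join(_TABLE_COLUMNS)]
    for contig in contigs:
        for c in contig.calls:
            lines.append(
                "\t".join(
                    (c.contig_id, str(c.start), str(c.end), c.strand,
                     c.kind, c.isotype, c.anticodon)
                )
            )
    return "\n".join(lines) + "\n"


# --- genome FASTA -------------------------------------------------------

def read_fasta(text: str) -> dict[str, str]:
    """Read FASTA into an ordered ``{contig_id: SEQUENCE}`` mapping.

    Identifiers are the first whitespace-delimited header token; sequences
    are uppercased. Duplicate identifiers and empty records are errors.
    """
    result: dict[str, str] = {}
    for record in SeqIO.parse(StringIO(text), "fasta"):
        if record.id in result:
            raise ParseError(f"duplicate FASTA identifier {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ParseError(f"empty FASTA record {record.id!r}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ParseError(
                f"record {record.id!r}: non-ACGTN characters {sorted(bad)}"
            )
        result[record.id] = seq
    return result


# --- report -------------------------------------------------------------

_REPORT_HEADER = (
    "genome", "total_trnas", "array_trnas", "array_length",
    "begin", "end", "density", "contig", "array",
)


def write_report(rows: list[ReportRow]) -> str:
    """Render report rows as TSV with a header line.

    Densities are printed to two decimals and ordinals as ``#1, #2, …``;
    ordinals must be consecutive from 1 within each genome.
    """
    _check_ordinals(rows)
    lines = ["\t".join(_REPORT_HEADER)]
    for r in rows:
        if r.has_array:
            lines.append(
                "\t".join(
                    (r.genome_id, str(r.total_trnas), str(r.array_trna_count),
                     str(r.array_length), str(r.begin), str(r.end),
                     f"{r.density:.2f}", str(r.contig_number),
                     f"#{r.array_ordinal}")
                )
            )
        else:
            lines.append(
                "\t".join((r.genome_id, str(r.total_trnas)) + ("",) * 7)
            )
    return "\n".join(lines) + "\n"


def _check_ordinals(rows: list[ReportRow]) -> None:
    per_genome: dict[str, list[int]] = {}
    for r in rows:
        if r.has_array:
            per_genome.setdefault(r.genome_id, []).append(r.array_ordinal)
    for gid, ordinals in per_genome.items():
        if ordinals != list(range(1, len(ordinals) + 1)):
            raise ValueError(
                f"genome {gid}: ordinals {ordinals} not consecutive from 1"
            )


def parse_report(text: str) -> list[ReportRow]:
    """Re-read a report written by :func:`write_report`.

    Densities come back rounded to the two printed decimals; the row
    consistency check therefore re-derives density from the integer fields.
    """
    rows: list[ReportRow] = []
    lines = text.splitlines()
    if not lines or tuple(lines[0].split("\t")) != _REPORT_HEADER:
        raise ParseError("missing or malformed report header")
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != len(_REPORT_HEADER):
            raise ParseError(f"line {lineno}: wrong column count")
        gid, total = fields[0], int(fields[1])
        if all(f == "" for f in fields[2:]):
            rows.append(ReportRow(gid, total))
            continue
        count = int(fields[2])
        length = int(fields[3])
        begin, end = int(fields[4]), int(fields[5])
        contig = int(fields[7])
        ordinal = int(fields[8].lstrip("#"))
        density = count / (length / 1000)  # full precision re-derived
        rows.append(
            ReportRow(gid, total, count, length, begin, end, density,
                      contig, ordinal)
        )
    return rows
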