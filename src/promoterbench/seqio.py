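"""Genome, annotation and dataset I/O.

All coordinates inside the package are 0-based half-open on the forward
strand.  The 1-based "+1 TSS" convention used by promoter annotation
formats (SGA) is converted at the parse/format boundary and nowhere else.

Sequences are uppercased on read; IUPAC ambiguity codes outside
``{A, C, G, T}`` are degraded to ``N`` so that real (soft-masked,
ambiguity-containing) genomes parse without special cases.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

# Every IUPAC nucleotide code that is not a concrete base becomes N.
_IUPAC_TO_N = str.maketrans(
    {c: "N" for c in "RYSWKMBDHVUN"} | {c.lower(): "N" for c in "RYSWKMBDHVU"}
)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when an input file does not match its declared format."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome-like sequence over ``{A, C, G, T, N}``."""

    name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("sequence name must be non-empty")
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise ValueError(f"invalid bases in {self.name!r}: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class TssAnnotation:
    """A strand-aware transcription start site (0-based forward-strand index)."""

    chrom: str
    pos0: int
    strand: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.pos0}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Length of the intersection with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def normalize_bases(raw: str) -> str:
    """Uppercase and degrade non-ACGT IUPAC codes to N."""
    out = raw.upper().translate(_IUPAC_TO_N)
    bad = set(out) - VALID_BASES
    if bad:
        raise ParseError(f"characters not in the nucleotide alphabet: {sorted(bad)}")
    return out


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into :class:`GenomeSequence` records."""
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', "
                    f"got {line.strip()[:30]!r}"
                )
            break
        else:
            raise ParseError(f"{path}: line 1: empty file, no FASTA records")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeSequence(name=rec.id, bases=normalize_bases(str(rec.seq))))
    if not records:
        raise ParseError(f"{path}: line 1: no FASTA records parsed")
    return records


def write_fasta(path: str | Path, seqs: Iterable[GenomeSequence], width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(s.bases), id=s.name, description="") for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def reverse_complement(seq: str) -> str:
    """Reverse complement over ``{A, C, G, T, N}``; N is a fixed point."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"cannot complement characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def extract_window(genome: GenomeSequence, iv: Interval) -> str:
    """Substring ``[start, end)``; the reverse complement for strand '-'.

    Out-of-bounds intervals raise instead of clipping silently.
    """
    if iv.end > genome.length:
        raise IndexError(
            f"interval [{iv.start}, {iv.end}) out of bounds for "
            f"{genome.name} of length {genome.length}"
        )
    s = genome.bases[iv.start : iv.end]
    return reverse_complement(s) if iv.strand == "-" else s


def _parse_sga_line(fields: list[str], lineno: int, path: Path) -> TssAnnotation:
    if len(fields) < 5:
        raise ParseError(f"{path}: line {lineno}: SGA needs >= 5 columns, got {len(fields)}")
    chrom, feature, pos_s, strand, _count = fields[:5]
    label = fields[5] if len(fields) > 5 else feature
    try:
        pos1 = int(pos_s)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: non-integer position {pos_s!r}") from None
    if strand not in ("+", "-"):
        raise ParseError(f"{path}: line {lineno}: unknown strand symbol {strand!r}")
    if pos1 < 1:
        raise ParseError(f"{path}: line {lineno}: 1-based position must be >= 1")
    return TssAnnotation(chrom=chrom, pos0=pos1 - 1, strand=strand, label=label)


def _parse_bed_line(fields: list[str], lineno: int, path: Path) -> TssAnnotation:
    if len(fields) < 6:
        raise ParseError(f"{path}: line {lineno}: BED6 needs 6 columns, got {len(fields)}")
    chrom, start_s, end_s, name, _score, strand = fields[:6]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ParseError(
            f"{path}: line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
        ) from None
    if strand not in ("+", "-"):
        raise ParseError(f"{path}: line {lineno}: unknown strand symbol {strand!r}")
    if not 0 <= start < end:
        raise ParseError(f"{path}: line {lineno}: require 0 <= start < end")
    # TSS = first transcribed base: feature start on '+', feature end - 1 on '-'.
    pos0 = start if strand == "+" else end - 1
    return TssAnnotation(chrom=chrom, pos0=pos0, strand=strand, label=name)


def parse_tss_annotations(path: str | Path, dialect: str) -> list[TssAnnotation]:
    """Parse TSS annotations from an SGA or BED6 file.

    SGA columns: seq-id, feature, 1-based position, strand, count[, name].
    BED: the TSS is the first base of the feature on '+' and the last on '-'.
    """
    path = Path(path)
    if dialect not in ("sga", "bed"):
        raise ValueError(f"dialect must be 'sga' or 'bed', got {dialect!r}")
    parse_line = _parse_sga_line if dialect == "sga" else _parse_bed_line
    out: list[TssAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            out.append(parse_line(line.split("\t"), lineno, path))
    return out


def write_sga(path: str | Path, annots: Iterable[TssAnnotation], feature: str = "TSS") -> None:
    with open(path, "w") as fh:
        for a in annots:
            fh.write(f"{a.chrom}\t{feature}\t{a.pos0 + 1}\t{a.strand}\t1\t{a.label}\n")
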