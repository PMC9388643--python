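"""Genome-annotation I/O and validated in-memory transcript/gene models.

All coordinates are 0-based half-open internally.  GTF (1-based, closed)
and BED (0-based, half-open) conversions happen only at the file boundary,
so downstream interval arithmetic never deals with off-by-one cases.

Strand is one of ``"+"``, ``"-"`` or ``"."``; ``"."`` means *unknown
orientation* (e.g. transcripts assembled exclusively from unstranded
single-end libraries) and downstream operations document how they treat it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

VALID_STRANDS = ("+", "-", ".")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AnnotationError(Exception):
    """Base class for annotation I/O problems."""


class ParseError(AnnotationError):
    """A malformed record in an annotation file; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class ValidationError(AnnotationError):
    """An in-memory model violating its invariants."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on one chromosome strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_bookended(exons: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge exactly-adjacent exons; reject overlapping ones.

    Input must already be sorted by start and share chrom/strand.
    """
    merged: list[GenomicInterval] = []
    for ex in exons:
        if merged and ex.start < merged[-1].end:
            raise ValidationError(
                f"overlapping exons {merged[-1]} and {ex} within one transcript"
            )
        if merged and ex.start == merged[-1].end:
            prev = merged.pop()
            ex = replace(prev, end=ex.end)
        merged.append(ex)
    return merged


@dataclass
class TranscriptModel:
    """An ordered exon chain on one chromosome/strand, optionally with its
    mature (spliced, strand-oriented) nucleotide sequence."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    sequence: str | None = None

    def __post_init__(self):
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"{self.transcript_id}: exons on multiple chroms/strands "
                f"({chroms}, {strands})"
            )
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValidationError(f"{self.transcript_id}: exons not sorted by start")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"{self.transcript_id}: overlapping exons {a} and {b}"
                )
        if self.sequence is not None and len(self.sequence) != self.exonic_length:
            raise ValidationError(
                f"{self.transcript_id}: sequence length {len(self.sequence)} != "
                f"exonic length {self.exonic_length}"
            )

    @classmethod
    def build(
        cls,
        transcript_id: str,
        gene_id: str,
        exons: Iterable[GenomicInterval],
        sequence: str | None = None,
    ) -> "TranscriptModel":
        """Sort exons, merge bookended ones, then validate."""
        exons = sorted(exons, key=lambda e: e.start)
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"{transcript_id}: exons on multiple chroms/strands "
                f"({chroms}, {strands})"
            )
        return cls(transcript_id, gene_id, merge_bookended(exons), sequence)

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]
    biotype_label: str | None = None  # coding / lncRNA / other

    def __post_init__(self):
        if not self.transcripts:
            raise ValidationError(f"{self.gene_id}: gene needs >=1 transcript")
        if any(t.gene_id != self.gene_id for t in self.transcripts):
            raise ValidationError(f"{self.gene_id}: transcripts with foreign gene_id")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.transcripts[0].strand)


@dataclass
class SampleMetadata:
    sample_id: str
    tissue: str
    age_days: int
    condition: str = "control"
    library_layout: str = "paired-end"

    def __post_init__(self):
        if self.age_days < 0:
            raise ValidationError(f"{self.sample_id}: age_days must be >= 0")
        if not self.tissue:
            raise ValidationError(f"{self.sample_id}: tissue must be non-empty")


def derive_introns(t: TranscriptModel) -> list[GenomicInterval]:
    """Gaps between consecutive exons; empty for mono-exonic transcripts."""
    return [
        GenomicInterval(t.chrom, a.end, b.start, t.strand)
        for a, b in zip(t.exons, t.exons[1:])
    ]


def extract_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Concatenated exon sequence, reverse-complemented on the minus strand.

    Unknown strand (".") is treated as plus.
    """
    if t.chrom not in genome:
        raise ValidationError(f"{t.transcript_id}: chrom {t.chrom!r} not in genome")
    chrom_seq = genome[t.chrom]
    for ex in t.exons:
        if ex.end > len(chrom_seq):
            raise ValidationError(
                f"{t.transcript_id}: exon {ex.start}-{ex.end} beyond chrom "
                f"length {len(chrom_seq)}"
            )
    seq = "".join(chrom_seq[e.start : e.end] for e in t.exons)
    return reverse_complement(seq) if t.strand == "-" else seq


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " not in part:
            raise ValueError(f"bad GTF attribute {part!r}")
        key, value = part.split(" ", 1)
        attrs[key] = value.strip().strip('"')
    return attrs


def _parse_gff3_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.strip().rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"bad GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key] = value
    return attrs


def _iter_feature_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", lineno
                )
            yield lineno, fields


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a GTF or GFF3 file into GeneModels (exon features only).

    GTF attributes (``key "value";``) are detected per record; GFF3 records
    may name their transcript via ``transcript_id`` or ``Parent``.  The
    1-based closed coordinates become 0-based half-open; bookended exons are
    merged, overlapping exons rejected.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    gene_of_tx: dict[str, str] = {}
    tx_parent: dict[str, str] = {}  # GFF3 mRNA ID -> gene ID
    order: list[str] = []

    for lineno, f in _iter_feature_lines(path):
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, raw = f
        try:
            attrs = (
                _parse_gff3_attributes(raw) if "=" in raw.split(";")[0]
                else _parse_gtf_attributes(raw)
            )
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
        if feature in ("mRNA", "transcript") and "ID" in attrs:
            tx_parent[attrs["ID"]] = attrs.get("Parent", attrs["ID"])
        if feature != "exon":
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"non-integer coordinates {start_s!r}/{end_s!r}", lineno) from exc
        if strand not in VALID_STRANDS:
            raise ParseError(f"invalid strand {strand!r}", lineno)
        tid = attrs.get("transcript_id") or attrs.get("Parent")
        if tid is None:
            raise ParseError("exon without transcript_id/Parent attribute", lineno)
        gid = attrs.get("gene_id")
        try:
            interval = GenomicInterval(chrom, start - 1, end, strand)
        except ValidationError as exc:
            raise ParseError(str(exc), lineno) from exc
        if tid not in exons_by_tx:
            exons_by_tx[tid] = []
            order.append(tid)
        exons_by_tx[tid].append(interval)
        if gid is not None:
            gene_of_tx[tid] = gid

    genes: dict[str, list[TranscriptModel]] = {}
    gene_order: list[str] = []
    for tid in order:
        gid = gene_of_tx.get(tid) or tx_parent.get(tid) or tid
        tx = TranscriptModel.build(tid, gid, exons_by_tx[tid])
        if gid not in genes:
            genes[gid] = []
            gene_order.append(gid)
        genes[gid].append(tx)
    return [GeneModel(gid, genes[gid]) for gid in gene_order]


def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    return [t for g in read_annotation(path) for t in g.transcripts]


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "strictlnc",
) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for ex in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


def write_bed6(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """One BED6 line per transcript span (browser-track friendly)."""
    with open(path, "w") as fh:
        for t in transcripts:
            s = t.span
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{t.transcript_id}\t0\t{s.strand}\n"
            )


def write_bed12(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            s = t.span
            sizes = ",".join(str(len(e)) for e in t.exons) + ","
            starts = ",".join(str(e.start - s.start) for e in t.exons) + ","
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{t.transcript_id}\t0\t{s.strand}\t"
                f"{s.start}\t{s.start}\t0\t{len(t.exons)}\t{sizes}\t{starts}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequential (index-free) FASTA parse into an id -> sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def gtf_round_trip(transcripts: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    """Write transcripts to GTF text and parse them back (testing aid)."""
    buf = io.StringIO()
    for t in transcripts:
        for ex in t.exons:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            buf.write(
                f"{ex.chrom}\tstrictlnc\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                f"{ex.strand}\t.\t{attrs}\n"
            )
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".gtf", delete=False) as tmp:
        tmp.write(buf.getvalue())
        name = tmp.name
    try:
        return read_transcripts(name)
    finally:
        os.unlink(name)
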