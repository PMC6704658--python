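"""Parsers for GFF3/GFF2, FASTA, and NCBI assembly metadata files.

Everything here produces :mod:`genoquery.schema` records. The GFF parser is
deliberately line-oriented: it keeps file order within each seqid, reports
malformed lines by line number, percent-decodes attribute tags and values
(so an encoded ``%3B`` never splits an attribute), and falls back to the
GFF2/GTF ``tag value`` attribute dialect when the column contains no ``=``.

Bulk ingestion is driven by a manifest TSV with one row per genome:
``accession  gff  stats  report  fasta  lineage`` where fasta may be ``-``
(absent) and lineage is a ``;``-joined clade list, root to leaf. All readers
accept plain or gzip-compressed files transparently.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, TextIO, Union
from urllib.parse import unquote

from Bio import SeqIO

from .schema import (
    AssemblerRec,
    AssemblyMeta,
    AttributeRec,
    FeatureRec,
    GenomeRecord,
    SequenceRec,
    validate,
)

__all__ = [
    "IngestError",
    "AssemblyHeaderMeta",
    "ManifestRow",
    "parse_gff3",
    "parse_assembly_stats",
    "parse_assembly_report",
    "read_fasta",
    "build_genome_record",
    "read_manifest",
    "ingest_manifest",
    "open_text",
]


class IngestError(ValueError):
    """Raised for malformed input files; the message names the location."""


@dataclass
class AssemblyHeaderMeta:
    """Header metadata parsed from an NCBI assembly_report.txt file."""

    assembler_names: list[str] = field(default_factory=list)
    assembler_descs: list[str] = field(default_factory=list)
    date_year: Optional[int] = None
    organism_name: Optional[str] = None
    taxid: Optional[int] = None


def open_text(path: Union[str, os.PathLike]) -> TextIO:
    """Open a text file, decompressing transparently if gzip-compressed."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


def _parse_attributes(col9: str, lineno: int) -> tuple[list[AttributeRec], Optional[str]]:
    """Split column 9 into attribute records; returns (attributes, parent).

    GFF3 style (tag=value) when any '=' is present, otherwise GFF2/GTF style
    (tag value, values possibly double-quoted). Percent-decoding is applied
    after splitting, so encoded separators never split an attribute.
    """
    attrs: list[AttributeRec] = []
    parent: Optional[str] = None
    if col9 in (".", ""):
        return attrs, parent
    gff3_style = "=" in col9
    for chunk in col9.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if gff3_style:
            tag, sep, value = chunk.partition("=")
            if not sep:
                # trailing flag-like token in an otherwise GFF3 column
                tag, value = chunk, ""
        else:
            tag, _, value = chunk.partition(" ")
            value = value.strip().strip('"')
        tag = unquote(tag.strip())
        value = unquote(value)
        if not tag:
            raise IngestError(f"line {lineno}: empty attribute tag")
        attrs.append(AttributeRec(tag=tag, value=value))
        if tag == "Parent":
            parent = value
    return attrs, parent


def parse_gff3(stream: Union[TextIO, Iterable[str]]) -> dict[str, list[FeatureRec]]:
    """Parse GFF3 (or GFF2/GTF) text into seqid -> [FeatureRec] in file order.

    Lines starting with '#' are directives/comments; everything after a
    ``##FASTA`` directive is ignored. Malformed lines raise
    :class:`IngestError` naming the line number.
    """
    out: dict[str, list[FeatureRec]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if line.startswith("##FASTA"):
            break
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise IngestError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(cols)}")
        seqid, source, ftype, start_s, end_s, score_s, strand, phase_s, col9 = cols
        try:
            start = int(start_s)
            end = int(end_s)
        except ValueError:
            raise IngestError(
                f"line {lineno}: non-integer start/end ({start_s!r}, {end_s!r})") from None
        score = None if score_s == "." else float(score_s)
        phase = None if phase_s == "." else int(phase_s)
        attrs, parent = _parse_attributes(col9, lineno)
        feat = FeatureRec(
            seqid=unquote(seqid), source=unquote(source), ftype=ftype,
            start=start, end=end, score=score, strand=strand, phase=phase,
            attributes=attrs, parent=parent,
        )
        out.setdefault(feat.seqid, []).append(feat)
    return out


_STAT_FIELD = {
    "total-length": "total_length",
    "total-gap-length": "total_gap_length",
    "scaffold-count": "scaffold_count",
    "scaffold-N50": "scaffold_n50",
    "contig-count": "contig_count",
    "contig-N50": "contig_n50",
}


def parse_assembly_stats(stream: Union[TextIO, Iterable[str]]) -> AssemblyMeta:
    """Parse an NCBI assembly_stats.txt file into a partial AssemblyMeta.

    Only genome-wide rows (first three columns ``all all all``) are read;
    statistics not present default to 0. A file with no such rows is
    rejected.
    """
    meta = AssemblyMeta()
    saw_all = False
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 5:
            continue
        if cols[0] == "all" and cols[1] == "all" and cols[2] == "all":
            saw_all = True
            attr = _STAT_FIELD.get(cols[3])
            if attr is not None:
                try:
                    setattr(meta, attr, int(cols[4]))
                except ValueError:
                    raise IngestError(
                        f"non-integer value for statistic {cols[3]}: {cols[4]!r}") from None
    if not saw_all:
        raise IngestError("not an assembly stats file (no 'all all all' rows)")
    return meta


def _split_assembler(entry: str) -> tuple[str, str]:
    """Split 'SOAPdenovo v. 2.04' into (name, version description)."""
    for marker in (" v. ", " version "):
        idx = entry.find(marker)
        if idx >= 0:
            return entry[:idx].strip(), entry[idx + 1:].strip()
    return entry.strip(), ""


def parse_assembly_report(stream: Union[TextIO, Iterable[str]]) -> AssemblyHeaderMeta:
    """Parse the header block of an NCBI assembly_report.txt file.

    Recognizes '# Assembly method:', '# Date:', '# Organism name:' and
    '# Taxid:'; absent headers leave the corresponding fields empty.
    """
    meta = AssemblyHeaderMeta()
    for line in stream:
        line = line.rstrip("\n")
        if not line.startswith("#"):
            continue
        body = line.lstrip("#").strip()
        key, sep, value = body.partition(":")
        if not sep:
            continue
        key = key.strip().lower()
        value = value.strip()
        if key == "assembly method" and value:
            for entry in value.split(";"):
                entry = entry.strip()
                if not entry:
                    continue
                name, desc = _split_assembler(entry)
                meta.assembler_names.append(name)
                meta.assembler_descs.append(desc)
        elif key == "date" and len(value) >= 4 and value[:4].isdigit():
            meta.date_year = int(value[:4])
        elif key == "organism name":
            meta.organism_name = value or None
        elif key == "taxid" and value.isdigit():
            meta.taxid = int(value)
    return meta


def read_fasta(stream: Union[TextIO, IO[str]]) -> list[tuple[str, str]]:
    """Read FASTA text into (header, uppercased residue string) pairs."""
    if not hasattr(stream, "read"):
        stream = io.StringIO("".join(stream))
    text = stream.read()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise IngestError("sequence data before any FASTA header")
    handle = io.StringIO(text)
    return [(rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def build_genome_record(
    gff: dict[str, list[FeatureRec]],
    stats: AssemblyMeta,
    header_meta: AssemblyHeaderMeta,
    fasta_pairs: Optional[list[tuple[str, str]]] = None,
    lineage: Optional[list[str]] = None,
    accession: str = "",
    taxid: Optional[int] = None,
    organism_name: Optional[str] = None,
) -> GenomeRecord:
    """Assemble a validated GenomeRecord from parsed components.

    One SequenceRec is created per seqid seen in the GFF mapping or the
    FASTA (union), with features attached by seqid. The stats file is
    authoritative for assembly numbers; assembler names/descs and the
    release year come from the report header.
    """
    if not accession:
        raise IngestError("accession must be non-empty")
    fasta_by_id: dict[str, str] = {}
    fasta_order: list[str] = []
    for header, seq in (fasta_pairs or []):
        seqid = header.split()[0] if header.split() else header
        if seqid in fasta_by_id:
            raise IngestError(f"duplicate seqid in FASTA: {seqid!r}")
        fasta_by_id[seqid] = seq
        fasta_order.append(seqid)
    seq_order = list(fasta_order)
    for seqid in gff:
        if seqid not in fasta_by_id:
            seq_order.append(seqid)
    sequences = []
    for seqid in seq_order:
        residues = fasta_by_id.get(seqid)
        sequences.append(SequenceRec(
            header=seqid,
            accession=seqid,
            length=len(residues) if residues is not None else 0,
            features=list(gff.get(seqid, [])),
            seq=residues,
        ))
    assembly = AssemblyMeta(
        assemblers=[
            AssemblerRec(name=n, desc=d)
            for n, d in zip(header_meta.assembler_names, header_meta.assembler_descs)
        ],
        total_length=stats.total_length,
        total_gap_length=stats.total_gap_length,
        scaffold_n50=stats.scaffold_n50,
        scaffold_count=stats.scaffold_count,
        contig_n50=stats.contig_n50,
        contig_count=stats.contig_count,
    )
    record = GenomeRecord(
        refseq_accession=accession,
        taxid=taxid if taxid is not None else (header_meta.taxid or 1),
        organism_name=organism_name or header_meta.organism_name or "",
        lineage=list(lineage or []),
        release_year=header_meta.date_year or 0,
        assembly=assembly,
        sequences=sequences,
    )
    violations = validate(record)
    if violations:
        raise IngestError(
            f"assembled record for {accession} is invalid: " + "; ".join(violations))
    return record


@dataclass(frozen=True)
class ManifestRow:
    """One corpus-manifest line: file paths and lineage for a genome."""

    accession: str
    gff_path: str
    stats_path: str
    report_path: str
    fasta_path: Optional[str]
    lineage: tuple[str, ...]


def read_manifest(path: Union[str, os.PathLike]) -> list[ManifestRow]:
    """Read a corpus manifest TSV; '-' or empty fasta column means no FASTA."""
    base = os.path.dirname(os.fspath(path))
    rows: list[ManifestRow] = []
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise IngestError(
                    f"manifest line {lineno}: expected 6 columns, got {len(cols)}")
            accession, gff, stats, report, fasta, lineage = cols
            resolve = lambda p: p if os.path.isabs(p) else os.path.join(base, p)
            rows.append(ManifestRow(
                accession=accession,
                gff_path=resolve(gff),
                stats_path=resolve(stats),
                report_path=resolve(report),
                fasta_path=resolve(fasta) if fasta not in ("", "-") else None,
                lineage=tuple(c for c in lineage.split(";") if c),
            ))
    return rows


def ingest_manifest(path: Union[str, os.PathLike]) -> Iterator[GenomeRecord]:
    """Yield one GenomeRecord per manifest row, in manifest order."""
    for row in read_manifest(path):
        with open_text(row.gff_path) as fh:
            gff = parse_gff3(fh)
        with open_text(row.stats_path) as fh:
            stats = parse_assembly_stats(fh)
        with open_text(row.report_path) as fh:
            header_meta = parse_assembly_report(fh)
        fasta_pairs = None
        if row.fasta_path is not None:
            with open_text(row.fasta_path) as fh:
                fasta_pairs = read_fasta(fh)
        yield build_genome_record(
            gff, stats, header_meta, fasta_pairs,
            lineage=list(row.lineage), accession=row.accession,
        )
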