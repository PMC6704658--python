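"""Domain record types for genome annotation and assembly metadata.

One :class:`GenomeRecord` bundles everything known about a single genome
deposit: identifying metadata (RefSeq accession, taxonomy id, lineage,
release year), assembly-level statistics (:class:`AssemblyMeta`), and the
annotated sequences (:class:`SequenceRec`, each carrying its GFF feature
lines as :class:`FeatureRec`).

These are plain in-memory dataclasses; serialization lives in
:mod:`genoquery.store` and file parsing in :mod:`genoquery.ingest`.
Validation is non-throwing: :func:`validate` returns a list of violation
descriptions so callers can report all problems at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "AttributeRec",
    "FeatureRec",
    "SequenceRec",
    "AssemblerRec",
    "AssemblyMeta",
    "GenomeRecord",
    "validate",
]

STRANDS = ("+", "-", ".", "?")


@dataclass(frozen=True)
class AttributeRec:
    """One tag=value pair from a GFF attribute column (e.g. gbkey, ID)."""

    tag: str
    value: str


@dataclass
class FeatureRec:
    """One GFF feature line; coordinates are 1-based, inclusive on both ends."""

    seqid: str
    source: str
    ftype: str
    start: int
    end: int
    score: Optional[float] = None
    strand: str = "."
    phase: Optional[int] = None
    attributes: list[AttributeRec] = field(default_factory=list)
    parent: Optional[str] = None

    @property
    def length(self) -> int:
        """Feature span in bp (end - start + 1)."""
        return self.end - self.start + 1


@dataclass
class SequenceRec:
    """A sequence (scaffold/chromosome) with its features; residues optional."""

    header: str
    accession: str
    length: int = 0
    features: list[FeatureRec] = field(default_factory=list)
    seq: Optional[str] = None


@dataclass(frozen=True)
class AssemblerRec:
    """An assembly program associated with a genome (name + free-text details)."""

    name: str
    desc: str = ""


@dataclass
class AssemblyMeta:
    """Assembly-level statistics as reported in NCBI assembly_stats files.

    An unscaffolded assembly reports scaffold statistics equal to contig
    statistics (or all zeros when unknown); the stats file, not the
    sequences, is authoritative for these numbers.
    """

    assemblers: list[AssemblerRec] = field(default_factory=list)
    total_length: int = 0
    total_gap_length: int = 0
    scaffold_n50: int = 0
    scaffold_count: int = 0
    contig_n50: int = 0
    contig_count: int = 0


@dataclass
class GenomeRecord:
    """One genome: identifying metadata, assembly statistics, and sequences."""

    refseq_accession: str
    taxid: int
    organism_name: str = ""
    lineage: list[str] = field(default_factory=list)
    release_year: int = 0
    assembly: AssemblyMeta = field(default_factory=AssemblyMeta)
    sequences: list[SequenceRec] = field(default_factory=list)


def _validate_feature(f: FeatureRec, where: str, out: list[str]) -> None:
    if not (1 <= f.start <= f.end):
        out.append(f"{where}: start/end must satisfy 1 <= start <= end, got start={f.start} end={f.end}")
    if f.strand not in STRANDS:
        out.append(f"{where}: strand must be one of {STRANDS}, got {f.strand!r}")
    if f.phase is not None and f.phase not in (0, 1, 2):
        out.append(f"{where}: phase must be 0, 1 or 2 when present, got {f.phase}")
    for a in f.attributes:
        if not a.tag:
            out.append(f"{where}: attribute tag must be non-empty")


def _validate_assembly(m: AssemblyMeta, out: list[str]) -> None:
    for name in ("total_length", "total_gap_length", "scaffold_n50",
                 "scaffold_count", "contig_n50", "contig_count"):
        v = getattr(m, name)
        if v < 0:
            out.append(f"assembly.{name}: must be non-negative, got {v}")
    if m.total_gap_length > m.total_length:
        out.append(
            f"assembly.total_gap_length: exceeds total_length ({m.total_gap_length} > {m.total_length})")
    if m.scaffold_n50 > m.total_length:
        out.append(
            f"assembly.scaffold_n50: exceeds total_length ({m.scaffold_n50} > {m.total_length})")
    if m.scaffold_n50 != 0 and m.contig_n50 > m.scaffold_n50:
        out.append(
            f"assembly.contig_n50: exceeds scaffold_n50 ({m.contig_n50} > {m.scaffold_n50})")
    if m.scaffold_count > 0 and m.contig_count > 0 and m.scaffold_count > m.contig_count:
        out.append(
            f"assembly.scaffold_count: exceeds contig_count ({m.scaffold_count} > {m.contig_count})")
    for i, a in enumerate(m.assemblers):
        if not a.name:
            out.append(f"assembly.assemblers[{i}].name: must be non-empty")


def validate(record: GenomeRecord) -> list[str]:
    """Check every schema invariant; return a description per violation.

    Pure and non-throwing: an empty list means the record is valid. Each
    violation names the offending field and the broken rule.
    """
    out: list[str] = []
    if not record.refseq_accession:
        out.append("refseq_accession: must be non-empty")
    if record.taxid < 1:
        out.append(f"taxid: must be >= 1, got {record.taxid}")
    if not record.lineage:
        out.append("lineage: must be non-empty")
    if not (1980 <= record.release_year <= 2100) and record.release_year != 0:
        out.append(f"release_year: must be in [1980, 2100], got {record.release_year}")
    _validate_assembly(record.assembly, out)
    for si, s in enumerate(record.sequences):
        where = f"sequences[{si}]"
        if s.length < 0:
            out.append(f"{where}.length: must be non-negative, got {s.length}")
        if s.seq is not None and len(s.seq) != s.length:
            out.append(
                f"{where}.seq: residue string length {len(s.seq)} != declared length {s.length}")
        for fi, f in enumerate(s.features):
            _validate_feature(f, f"{where}.features[{fi}]", out)
            if s.length > 0 and f.end > s.length:
                out.append(
                    f"{where}.features[{fi}].end: {f.end} beyond sequence length {s.length}")
    return out
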