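"""Assembly statistics computed directly from sequence content.

Computes the standard contiguity metrics (total length, scaffold/contig
counts and N50s, total gap length) from FASTA residues when no NCBI stats
file is available, and writes them back out in the ``assembly_stats.txt``
dialect so they can round-trip through :func:`genoquery.ingest.parse_assembly_stats`.

A scaffold is split into contigs at maximal runs of ``N`` of length >=
``min_gap`` (default 10, the common NCBI convention); shorter N runs stay
inside contigs and are not counted as gap. Total gap length counts only the
splitting runs.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence, TextIO

from .schema import AssemblyMeta

__all__ = ["split_contigs", "compute_n50", "stats_from_fasta", "write_stats_file"]

DEFAULT_MIN_GAP = 10


def split_contigs(residues: str, min_gap: int = DEFAULT_MIN_GAP) -> tuple[list[int], int]:
    """Split a scaffold at N runs of length >= min_gap.

    Returns ``(contig_lengths, total_gap_length)`` where contig lengths are
    the non-gap segment lengths in scaffold order (empty segments dropped)
    and the gap total sums only the splitting runs.
    """
    if not residues:
        return [], 0
    contigs: list[int] = []
    gap_total = 0
    pos = 0
    up = residues.upper()
    for m in re.finditer(r"N{%d,}" % min_gap, up):
        seg = m.start() - pos
        if seg > 0:
            contigs.append(seg)
        gap_total += m.end() - m.start()
        pos = m.end()
    if pos < len(up):
        contigs.append(len(up) - pos)
    return contigs, gap_total


def compute_n50(lengths: Sequence[int]) -> int:
    """N50: the largest length at which the descending cumulative sum first
    reaches at least half the total.

    Uses exact integer comparison (2 * cumulative >= total) to avoid float.
    """
    if not lengths:
        raise ValueError("no sequences")
    total = sum(lengths)
    cum = 0
    for L in sorted(lengths, reverse=True):
        cum += L
        if 2 * cum >= total:
            return L
    raise AssertionError("unreachable: cumulative sum covers total")


def stats_from_fasta(
    fasta_pairs: Iterable[tuple[str, str]],
    min_gap: int = DEFAULT_MIN_GAP,
) -> AssemblyMeta:
    """Compute AssemblyMeta from (header, residues) pairs.

    Scaffold count/length include N gaps; contigs are pooled across
    scaffolds. The assemblers list is left empty (it comes from metadata,
    not sequence).
    """
    scaffold_lengths: list[int] = []
    contig_lengths: list[int] = []
    gap_total = 0
    for _header, seq in fasta_pairs:
        scaffold_lengths.append(len(seq))
        contigs, gaps = split_contigs(seq, min_gap)
        contig_lengths.extend(contigs)
        gap_total += gaps
    if not scaffold_lengths:
        raise ValueError("no sequences")
    return AssemblyMeta(
        assemblers=[],
        total_length=sum(scaffold_lengths),
        total_gap_length=gap_total,
        scaffold_n50=compute_n50(scaffold_lengths),
        scaffold_count=len(scaffold_lengths),
        contig_n50=compute_n50(contig_lengths) if contig_lengths else 0,
        contig_count=len(contig_lengths),
    )


_STAT_ROWS = (
    ("total-length", "total_length"),
    ("total-gap-length", "total_gap_length"),
    ("scaffold-count", "scaffold_count"),
    ("scaffold-N50", "scaffold_n50"),
    ("contig-count", "contig_count"),
    ("contig-N50", "contig_n50"),
)


def write_stats_file(meta: AssemblyMeta, handle: TextIO) -> None:
    """Write assembly statistics in the NCBI assembly_stats.txt dialect.

    Emits the genome-wide "all all all" rows that parse_assembly_stats reads
    back. total-gap-length counts only contig-splitting N runs (>= 10 N), not
    every ambiguous base.
    """
    handle.write("# Assembly Statistics Report\n")
    handle.write("# unit-name\tmolecule-name\trefseq-accn\tstatistic\tvalue\n")
    for stat_name, attr in _STAT_ROWS:
        handle.write(f"all\tall\tall\t{stat_name}\t{getattr(meta, attr)}\n")
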