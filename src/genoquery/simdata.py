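"""Synthetic RefSeq-like corpus generator with exact ground truth.

Generates, per genome: a GFF3 annotation (gene features with exon children
for eukaryote profiles; prokaryote profiles emit no exons), an NCBI-style
assembly_report.txt (assembler program, date, organism, taxid) and
assembly_stats.txt (total length, gap length, scaffold/contig counts and
N50s), a manifest row for bulk ingestion, and a truth-table row recording
the exact counts written — so every query result can be checked against
known values without downloading anything.

Distributions per clade profile:

* gene count, gene length, genome length, scaffold count — lognormal
  (a log-sd of 0 gives a degenerate, exact value);
* exons per gene — shifted negative binomial (minimum 1) with a stated
  mean and dispersion; dispersion <= 0 degenerates to the rounded mean;
* submission year and assembler — categorical draws, with assembler
  weights switching at the 2016 year boundary.

Gene coordinates are laid out non-overlapping left to right with 100 bp
spacers on a single annotation sequence, strands alternating; exons tile
their gene's span. The same seed reproduces a byte-identical directory
tree.
"""

from __future__ import annotations

import configparser
import os
from dataclasses import dataclass, field
from typing import Optional, TextIO, Union
from urllib.parse import quote

import numpy as np
import pandas as pd

from .asmstats import compute_n50
from .schema import FeatureRec

__all__ = [
    "CladeProfile", "TruthRow", "simulate_corpus", "expected_summaries",
    "write_gff3", "default_profiles", "load_profiles", "GENE_SPACER_BP",
]

GENE_SPACER_BP = 100
_GFF_ESCAPE_SAFE = " !\"#$'()*+-./:<>?@[]^_{|}~"  # GFF3 reserves ; = & , %


@dataclass
class CladeProfile:
    """Generating distributions for one clade's genomes."""

    clade_name: str
    lineage: list[str]
    n_genomes: int
    has_exons: bool = True
    gene_count_log_mean: float = 4.6
    gene_count_log_sd: float = 0.3
    exons_per_gene_mean: float = 3.0
    exons_per_gene_dispersion: float = 5.0
    gene_length_log_mean: float = 7.3
    gene_length_log_sd: float = 0.3
    genome_length_log_mean: float = 15.0
    genome_length_log_sd: float = 0.4
    scaffold_count_log_mean: float = 3.0
    scaffold_count_log_sd: float = 0.6
    year_weights: dict[int, float] = field(default_factory=lambda: {2014: 0.5, 2017: 0.5})
    assembler_weights_lt2016: dict[str, float] = field(
        default_factory=lambda: {"SOAPdenovo": 0.5, "AllPaths": 0.3, "Newbler": 0.2})
    assembler_weights_ge2016: dict[str, float] = field(
        default_factory=lambda: {"SPAdes": 0.6, "AllPaths": 0.2, "CLC": 0.2})
    taxid_base: int = 10000

    def gene_count_mean(self) -> float:
        """Mean of the generating lognormal for genes per genome."""
        return float(np.exp(self.gene_count_log_mean + self.gene_count_log_sd ** 2 / 2))

    def gene_count_sd(self) -> float:
        s2 = self.gene_count_log_sd ** 2
        return float(self.gene_count_mean() * np.sqrt(np.expm1(s2)))

    def validate(self) -> list[str]:
        out = []
        if self.n_genomes < 1:
            out.append(f"{self.clade_name}: n_genomes must be >= 1")
        if not self.lineage:
            out.append(f"{self.clade_name}: lineage must be non-empty")
        for label, weights in (
                ("year_weights", self.year_weights),
                ("assembler_weights_lt2016", self.assembler_weights_lt2016),
                ("assembler_weights_ge2016", self.assembler_weights_ge2016)):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                out.append(f"{self.clade_name}: {label} sum to {total}, expected 1")
        return out


@dataclass(frozen=True)
class TruthRow:
    """Exact per-genome ground truth matching the emitted files."""

    accession: str
    clade_name: str
    lineage: str  # ";"-joined, root to leaf
    release_year: int
    assembler_name: str
    gene_count: int
    exon_count: int
    mean_gene_length: float
    total_length: int
    total_gap_length: int
    scaffold_count: int
    scaffold_n50: int
    contig_count: int
    contig_n50: int


def _escape_attr(value: str) -> str:
    # interior spaces are legal GFF3; boundary spaces would be stripped by
    # whitespace-tolerant parsers, so they are percent-encoded
    out = quote(value, safe=_GFF_ESCAPE_SAFE)
    n_lead = len(out) - len(out.lstrip(" "))
    n_trail = len(out) - len(out.rstrip(" "))
    if n_lead:
        out = "%20" * n_lead + out[n_lead:]
    if n_trail and len(out) > n_lead:
        out = out[:len(out) - n_trail] + "%20" * n_trail
    return out


def write_gff3(features: list[FeatureRec], handle: TextIO) -> None:
    """Write features as GFF3 text that parse_gff3 round-trips exactly."""
    handle.write("##gff-version 3\n")
    for f in features:
        attrs = ";".join(f"{_escape_attr(a.tag)}={_escape_attr(a.value)}"
                         for a in f.attributes)
        handle.write("\t".join([
            f.seqid, f.source, f.ftype, str(f.start), str(f.end),
            "." if f.score is None else repr(f.score),
            f.strand,
            "." if f.phase is None else str(f.phase),
            attrs or ".",
        ]) + "\n")


def _draw_categorical(rng: np.random.Generator, weights: dict) -> object:
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _draw_count(rng: np.random.Generator, log_mean: float, log_sd: float,
                minimum: int = 1) -> int:
    if log_sd <= 0:
        return max(minimum, int(round(np.exp(log_mean))))
    return max(minimum, int(round(rng.lognormal(log_mean, log_sd))))


def _draw_exons(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if dispersion <= 0:
        return max(1, int(round(mean)))
    shifted = mean - 1.0
    if shifted <= 0:
        return 1
    p = dispersion / (dispersion + shifted)
    return 1 + int(rng.negative_binomial(dispersion, p))


def _gene_features(rng: np.random.Generator,
                   profile: CladeProfile) -> tuple[list[FeatureRec], int, int, float]:
    """Lay out gene/exon features; returns (features, genes, exons, mean span)."""
    from .schema import AttributeRec

    n_genes = _draw_count(rng, profile.gene_count_log_mean, profile.gene_count_log_sd)
    features: list[FeatureRec] = []
    pos = 1
    exon_total = 0
    span_total = 0
    seqid = "annot_1"
    for gi in range(n_genes):
        length = _draw_count(rng, profile.gene_length_log_mean,
                             profile.gene_length_log_sd, minimum=60)
        start, end = pos, pos + length - 1
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"gene{gi}"
        features.append(FeatureRec(
            seqid=seqid, source="genoquery_sim", ftype="gene",
            start=start, end=end, strand=strand,
            attributes=[AttributeRec("ID", gene_id),
                        AttributeRec("gbkey", "Gene")],
        ))
        span_total += length
        if profile.has_exons:
            n_exons = min(_draw_exons(rng, profile.exons_per_gene_mean,
                                      profile.exons_per_gene_dispersion), length)
            bounds = [start + (length * j) // n_exons for j in range(n_exons + 1)]
            for ei in range(n_exons):
                features.append(FeatureRec(
                    seqid=seqid, source="genoquery_sim", ftype="exon",
                    start=bounds[ei], end=bounds[ei + 1] - 1, strand=strand,
                    attributes=[AttributeRec("ID", f"exon{gi}_{ei}"),
                                AttributeRec("Parent", gene_id)],
                    parent=gene_id,
                ))
            exon_total += n_exons
        pos = end + 1 + GENE_SPACER_BP
    mean_len = span_total / n_genes if n_genes else 0.0
    return features, n_genes, exon_total, mean_len


def _assembly_numbers(rng: np.random.Generator, profile: CladeProfile):
    """Synthesize scaffold/contig lengths and derive assembly statistics."""
    n_scaffolds = _draw_count(rng, profile.scaffold_count_log_mean,
                              profile.scaffold_count_log_sd)
    total = _draw_count(rng, profile.genome_length_log_mean,
                        profile.genome_length_log_sd,
                        minimum=n_scaffolds * 1000)
    props = rng.dirichlet(np.full(n_scaffolds, 5.0)) if n_scaffolds > 1 else np.array([1.0])
    lengths = np.maximum(1, np.floor(props * total).astype(int))
    lengths[0] += total - int(lengths.sum())  # make the sum exact
    scaffold_lengths = [int(x) for x in lengths]
    contig_lengths: list[int] = []
    gap_total = 0
    for L in scaffold_lengths:
        max_gaps = max(0, (L - 1) // 200)  # keep every contig >= ~100 bp
        n_gaps = int(min(rng.poisson(2.0), max_gaps))
        if n_gaps == 0:
            contig_lengths.append(L)
            continue
        gap_lens = [int(10 + rng.integers(0, 91)) for _ in range(n_gaps)]
        non_gap = L - sum(gap_lens)
        # distinct interior cut points guarantee every contig >= 1 bp
        cuts = sorted(int(c) + 1 for c in
                      rng.choice(non_gap - 1, size=n_gaps, replace=False))
        cuts = [0] + cuts + [non_gap]
        segs = [b - a for a, b in zip(cuts, cuts[1:])]
        contig_lengths.extend(segs)
        gap_total += sum(gap_lens)
    return {
        "total_length": sum(scaffold_lengths),
        "total_gap_length": gap_total,
        "scaffold_count": len(scaffold_lengths),
        "scaffold_n50": compute_n50(scaffold_lengths),
        "contig_count": len(contig_lengths),
        "contig_n50": compute_n50(contig_lengths),
    }


def _write_stats_file(path: str, stats: dict) -> None:
    rows = (("total-length", "total_length"),
            ("total-gap-length", "total_gap_length"),
            ("scaffold-count", "scaffold_count"),
            ("scaffold-N50", "scaffold_n50"),
            ("contig-count", "contig_count"),
            ("contig-N50", "contig_n50"))
    with open(path, "w", newline="\n") as fh:
        fh.write("# Assembly Statistics Report\n")
        fh.write("# unit-name\tmolecule-name\trefseq-accn\tstatistic\tvalue\n")
        for stat_name, key in rows:
            fh.write(f"all\tall\tall\t{stat_name}\t{stats[key]}\n")


def simulate_corpus(
    profiles: list[CladeProfile],
    seed: int,
    out_dir: Union[str, os.PathLike],
) -> tuple[str, pd.DataFrame]:
    """Generate a corpus under out_dir; returns (manifest path, truth table).

    Files per genome live in ``genomes/<accession>/``; the manifest TSV and
    truth TSV sit at the top of out_dir. Deterministic for a fixed seed.
    """
    problems = [p for profile in profiles for p in profile.validate()]
    if problems:
        raise ValueError("invalid profiles: " + "; ".join(problems))
    out_dir = os.fspath(out_dir)
    os.makedirs(os.path.join(out_dir, "genomes"), exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest_lines: list[str] = []
    truth_rows: list[TruthRow] = []
    genome_idx = 0
    for profile in profiles:
        for k in range(profile.n_genomes):
            accession = f"GCF_{900000000 + genome_idx:09d}.1"
            taxid = profile.taxid_base + k
            year = int(_draw_categorical(rng, profile.year_weights))
            weights = (profile.assembler_weights_ge2016 if year >= 2016
                       else profile.assembler_weights_lt2016)
            assembler = str(_draw_categorical(rng, weights))
            features, n_genes, n_exons, mean_len = _gene_features(rng, profile)
            stats = _assembly_numbers(rng, profile)

            gdir = os.path.join(out_dir, "genomes", accession)
            os.makedirs(gdir, exist_ok=True)
            gff_rel = f"genomes/{accession}/{accession}_genomic.gff"
            stats_rel = f"genomes/{accession}/{accession}_assembly_stats.txt"
            report_rel = f"genomes/{accession}/{accession}_assembly_report.txt"
            with open(os.path.join(out_dir, gff_rel), "w", newline="\n") as fh:
                write_gff3(features, fh)
            _write_stats_file(os.path.join(out_dir, stats_rel), stats)
            with open(os.path.join(out_dir, report_rel), "w", newline="\n") as fh:
                fh.write(f"# Assembly method: {assembler} v. 1.0\n")
                fh.write(f"# Date: {year}-06-15\n")
                fh.write(f"# Organism name: {profile.clade_name} sp. {k} (simulated)\n")
                fh.write(f"# Taxid: {taxid}\n")
            manifest_lines.append("\t".join([
                accession, gff_rel, stats_rel, report_rel, "-",
                ";".join(profile.lineage)]))
            truth_rows.append(TruthRow(
                accession=accession, clade_name=profile.clade_name,
                lineage=";".join(profile.lineage), release_year=year,
                assembler_name=assembler, gene_count=n_genes,
                exon_count=n_exons, mean_gene_length=mean_len,
                **stats,
            ))
            genome_idx += 1
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w", newline="\n") as fh:
        fh.write("\n".join(manifest_lines) + "\n")
    truth = pd.DataFrame([vars(r) for r in truth_rows])
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False,
                 lineterminator="\n")
    return manifest_path, truth


# ---------------------------------------------------------------------------
# oracle summaries over the truth table

def _bucket(year: int) -> str:
    return "ge2016" if year >= 2016 else "lt2016"


def _mean_sd(series: pd.Series) -> tuple[float, float]:
    if len(series) == 0:
        return float("nan"), 0.0
    sd = float(series.std(ddof=1)) if len(series) > 1 else 0.0
    return float(series.mean()), sd


def expected_summaries(truth: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summaries implied by the truth table, keyed like the query outputs.

    Genomes contribute to every clade on their lineage (matching the query
    semantics of indexing by lineage entries). Zero-gene genomes are
    excluded from gene-length and exons-per-gene means, zero-exon genomes
    from exon means; both stay in species counts. Spreads are sample
    standard deviations (0 for singleton groups).
    """
    df = truth.copy()
    df["bucket"] = df["release_year"].map(_bucket)
    df["clade"] = df["lineage"].str.split(";")
    df = df.explode("clade", ignore_index=True)
    df["exons_per_gene"] = df["exon_count"] / df["gene_count"].where(df["gene_count"] > 0)

    exon_rows = []
    for (clade, bucket), grp in df.groupby(["clade", "bucket"], sort=True):
        with_genes = grp[grp["gene_count"] > 0]
        with_exons = grp[grp["exon_count"] > 0]
        both = grp[(grp["gene_count"] > 0) & (grp["exon_count"] > 0)]
        gene_m, gene_s = _mean_sd(grp["gene_count"])
        len_m, len_s = _mean_sd(with_genes["mean_gene_length"])
        ex_m, ex_s = _mean_sd(with_exons["exon_count"])
        epg_m, epg_s = _mean_sd(both["exons_per_gene"])
        exon_rows.append({
            "clade": clade, "bucket": bucket, "species": len(grp),
            "gene_number_mean": gene_m, "gene_number_sd": gene_s,
            "gene_length_mean": len_m, "gene_length_sd": len_s,
            "exon_number_mean": ex_m, "exon_number_sd": ex_s,
            "exons_per_gene_mean": epg_m, "exons_per_gene_sd": epg_s,
            "n_with_exons": len(with_exons),
        })

    quality_rows = []
    stats_cols = ("total_length", "scaffold_count", "scaffold_n50",
                  "contig_count", "contig_n50")
    for (clade, bucket, asm), grp in df.groupby(
            ["clade", "bucket", "assembler_name"], sort=True):
        row = {"clade": clade, "bucket": bucket, "assembler": asm,
               "species": len(grp)}
        for col in stats_cols:
            m, s = _mean_sd(grp[col])
            row[f"{col}_mean"] = m
            row[f"{col}_sd"] = s
        quality_rows.append(row)

    year_counts = (df.groupby(["clade", "assembler_name", "release_year"], sort=True)
                   .size().rename("genomes").reset_index())
    return {
        "exon_stats": pd.DataFrame(exon_rows),
        "assembly_quality": pd.DataFrame(quality_rows),
        "assembler_year_counts": year_counts,
    }


# ---------------------------------------------------------------------------
# shipped configurations

def default_profiles() -> list[CladeProfile]:
    """Desk-scale corpus echoing the clade structure of a RefSeq snapshot.

    Exons-per-gene and gene-length scales follow the real clades (metazoan
    genes average ~18 exons, fungal ~3); per-genome gene counts are scaled
    down by roughly two orders of magnitude so a full corpus builds in
    seconds. Bacterial assembler mixes shift toward SPAdes at 2016.
    """
    years_rising = {2012: 0.06, 2013: 0.08, 2014: 0.12, 2015: 0.14,
                    2016: 0.16, 2017: 0.18, 2018: 0.26}
    return [
        CladeProfile(
            clade_name="Bacteria", lineage=["Bacteria"], n_genomes=120,
            has_exons=False,
            gene_count_log_mean=np.log(43.0), gene_count_log_sd=0.33,
            gene_length_log_mean=np.log(890.0), gene_length_log_sd=0.07,
            genome_length_log_mean=np.log(4.0e6), genome_length_log_sd=0.35,
            scaffold_count_log_mean=np.log(45.0), scaffold_count_log_sd=0.8,
            year_weights=years_rising,
            assembler_weights_lt2016={"SOAPdenovo": 0.35, "AllPaths": 0.3,
                                      "Newbler": 0.2, "CLC": 0.15},
            assembler_weights_ge2016={"SPAdes": 0.55, "CLC": 0.2,
                                      "SOAPdenovo": 0.15, "AllPaths": 0.1},
            taxid_base=20000),
        CladeProfile(
            clade_name="Archaea", lineage=["Archaea"], n_genomes=20,
            has_exons=False,
            gene_count_log_mean=np.log(29.0), gene_count_log_sd=0.28,
            gene_length_log_mean=np.log(851.0), gene_length_log_sd=0.05,
            genome_length_log_mean=np.log(2.9e6), genome_length_log_sd=0.3,
            scaffold_count_log_mean=np.log(20.0), scaffold_count_log_sd=0.7,
            year_weights=years_rising,
            assembler_weights_lt2016={"Newbler": 0.5, "SOAPdenovo": 0.5},
            assembler_weights_ge2016={"SPAdes": 0.7, "CLC": 0.3},
            taxid_base=30000),
        CladeProfile(
            clade_name="Fungi", lineage=["Eukaryota", "Fungi", "Ascomycota"],
            n_genomes=40,
            gene_count_log_mean=np.log(100.0), gene_count_log_sd=0.33,
            exons_per_gene_mean=2.9, exons_per_gene_dispersion=4.0,
            gene_length_log_mean=np.log(1600.0), gene_length_log_sd=0.11,
            genome_length_log_mean=np.log(2.9e7), genome_length_log_sd=0.45,
            scaffold_count_log_mean=np.log(140.0), scaffold_count_log_sd=0.9,
            year_weights=years_rising,
            assembler_weights_lt2016={"AllPaths": 0.4, "SOAPdenovo": 0.4,
                                      "Newbler": 0.2},
            assembler_weights_ge2016={"SPAdes": 0.5, "AllPaths": 0.3,
                                      "SOAPdenovo": 0.2},
            taxid_base=40000),
        CladeProfile(
            clade_name="Metazoa", lineage=["Eukaryota", "Metazoa", "Chordata"],
            n_genomes=40,
            gene_count_log_mean=np.log(249.0), gene_count_log_sd=0.38,
            exons_per_gene_mean=17.7, exons_per_gene_dispersion=6.0,
            gene_length_log_mean=np.log(23000.0), gene_length_log_sd=0.48,
            genome_length_log_mean=np.log(1.2e9), genome_length_log_sd=0.6,
            scaffold_count_log_mean=np.log(8000.0), scaffold_count_log_sd=1.0,
            year_weights=years_rising,
            assembler_weights_lt2016={"SOAPdenovo": 0.55, "AllPaths": 0.3,
                                      "Newbler": 0.15},
            assembler_weights_ge2016={"AllPaths": 0.45, "SOAPdenovo": 0.35,
                                      "Newbler": 0.2},
            taxid_base=50000),
        CladeProfile(
            clade_name="Viridiplantae",
            lineage=["Eukaryota", "Viridiplantae", "eudicotyledons"],
            n_genomes=20,
            gene_count_log_mean=np.log(430.0), gene_count_log_sd=0.45,
            exons_per_gene_mean=9.2, exons_per_gene_dispersion=8.0,
            gene_length_log_mean=np.log(4100.0), gene_length_log_sd=0.3,
            genome_length_log_mean=np.log(8.0e8), genome_length_log_sd=0.6,
            scaffold_count_log_mean=np.log(9000.0), scaffold_count_log_sd=1.0,
            year_weights=years_rising,
            assembler_weights_lt2016={"SOAPdenovo": 0.6, "Newbler": 0.4},
            assembler_weights_ge2016={"AllPaths": 0.5, "SPAdes": 0.5},
            taxid_base=60000),
    ]


def _parse_weights(text: str, cast=float) -> dict:
    out = {}
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.rpartition(":")
        out[key.strip()] = float(val)
    return out


def load_profiles(path: Union[str, os.PathLike]) -> list[CladeProfile]:
    """Load clade profiles from a plain-text config file.

    One ``[clade:<Name>]`` section per clade; keys mirror the CladeProfile
    fields (weights as ``key:prob`` comma lists; year weights use integer
    year keys). Unset keys keep the dataclass defaults.
    """
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)
    profiles: list[CladeProfile] = []
    for section in cp.sections():
        if not section.startswith("clade:"):
            raise ValueError(f"unexpected config section {section!r}")
        name = section.split(":", 1)[1]
        sec = cp[section]
        kwargs: dict = {
            "clade_name": name,
            "lineage": [c for c in sec.get("lineage", name).split(";") if c],
            "n_genomes": sec.getint("n_genomes", 10),
            "has_exons": sec.getboolean("has_exons", True),
        }
        for key in ("gene_count_log_mean", "gene_count_log_sd",
                    "exons_per_gene_mean", "exons_per_gene_dispersion",
                    "gene_length_log_mean", "gene_length_log_sd",
                    "genome_length_log_mean", "genome_length_log_sd",
                    "scaffold_count_log_mean", "scaffold_count_log_sd"):
            if key in sec:
                kwargs[key] = sec.getfloat(key)
        if "taxid_base" in sec:
            kwargs["taxid_base"] = sec.getint("taxid_base")
        if "year_weights" in sec:
            kwargs["year_weights"] = {int(k): v for k, v in
                                      _parse_weights(sec["year_weights"]).items()}
        if "assembler_weights_lt2016" in sec:
            kwargs["assembler_weights_lt2016"] = _parse_weights(
                sec["assembler_weights_lt2016"])
        if "assembler_weights_ge2016" in sec:
            kwargs["assembler_weights_ge2016"] = _parse_weights(
                sec["assembler_weights_ge2016"])
        profiles.append(CladeProfile(**kwargs))
    if not profiles:
        raise ValueError("config defines no [clade:...] sections")
    return profiles
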