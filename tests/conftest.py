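"""Shared fixtures: simulated corpora at several scales and comparison helpers."""

from __future__ import annotations

import math
import os

import numpy as np
import pytest

from genoquery import ingest, simdata, store
from genoquery.schema import (
    AssemblerRec, AssemblyMeta, AttributeRec, FeatureRec, GenomeRecord,
    SequenceRec,
)


def light_profiles() -> list[simdata.CladeProfile]:
    """A three-clade corpus with small per-genome gene counts (fast to build)."""
    years = {2013: 0.2, 2015: 0.2, 2016: 0.2, 2017: 0.2, 2018: 0.2}
    return [
        simdata.CladeProfile(
            clade_name="Bacteria", lineage=["Bacteria"], n_genomes=600,
            has_exons=False,
            gene_count_log_mean=math.log(20), gene_count_log_sd=0.3,
            gene_length_log_mean=math.log(900), gene_length_log_sd=0.1,
            genome_length_log_mean=math.log(4e6), genome_length_log_sd=0.3,
            scaffold_count_log_mean=math.log(30), scaffold_count_log_sd=0.6,
            year_weights=years,
            assembler_weights_lt2016={"AllPaths": 0.5, "SOAPdenovo": 0.5},
            assembler_weights_ge2016={"SPAdes": 0.7, "CLC": 0.3},
            taxid_base=20000),
        simdata.CladeProfile(
            clade_name="Fungi", lineage=["Eukaryota", "Fungi"], n_genomes=250,
            gene_count_log_mean=math.log(30), gene_count_log_sd=0.3,
            exons_per_gene_mean=3.0, exons_per_gene_dispersion=4.0,
            gene_length_log_mean=math.log(1500), gene_length_log_sd=0.15,
            genome_length_log_mean=math.log(3e7), genome_length_log_sd=0.4,
            scaffold_count_log_mean=math.log(100), scaffold_count_log_sd=0.7,
            year_weights=years,
            taxid_base=40000),
        simdata.CladeProfile(
            clade_name="Metazoa", lineage=["Eukaryota", "Metazoa"], n_genomes=150,
            gene_count_log_mean=math.log(25), gene_count_log_sd=0.3,
            exons_per_gene_mean=8.0, exons_per_gene_dispersion=6.0,
            gene_length_log_mean=math.log(8000), gene_length_log_sd=0.3,
            genome_length_log_mean=math.log(1e9), genome_length_log_sd=0.5,
            scaffold_count_log_mean=math.log(3000), scaffold_count_log_sd=0.8,
            year_weights=years,
            taxid_base=50000),
    ]


def degenerate_profile(n_genomes: int = 5) -> simdata.CladeProfile:
    """Exactly 10 genes of length 1000 and 2 exons per gene, year 2018."""
    return simdata.CladeProfile(
        clade_name="Testa", lineage=["Eukaryota", "Testa"], n_genomes=n_genomes,
        gene_count_log_mean=math.log(10), gene_count_log_sd=0.0,
        exons_per_gene_mean=2.0, exons_per_gene_dispersion=0.0,
        gene_length_log_mean=math.log(1000), gene_length_log_sd=0.0,
        genome_length_log_mean=math.log(2e6), genome_length_log_sd=0.0,
        scaffold_count_log_mean=math.log(3), scaffold_count_log_sd=0.0,
        year_weights={2018: 1.0},
        assembler_weights_ge2016={"SPAdes": 1.0},
        taxid_base=70000)


class Corpus:
    """Bundle of paths + truth table for a simulated, ingested corpus."""

    def __init__(self, out_dir: str, profiles, seed: int, block_records: int = 64):
        self.dir = str(out_dir)
        self.manifest, self.truth = simdata.simulate_corpus(
            profiles, seed=seed, out_dir=self.dir)
        self.db = os.path.join(self.dir, "db.bgsf")
        self.n_records = store.write_store(
            ingest.ingest_manifest(self.manifest), self.db,
            block_records=block_records)

    def records(self):
        return list(store.read_store(self.db))

    def gff_paths(self):
        out = []
        for root, _dirs, files in os.walk(self.dir):
            out.extend(os.path.join(root, f) for f in files if f.endswith(".gff"))
        return sorted(out)


@pytest.fixture(scope="session")
def light_corpus(tmp_path_factory) -> Corpus:
    """1,000 genomes over three clades."""
    return Corpus(tmp_path_factory.mktemp("light_corpus"), light_profiles(), seed=2024)


@pytest.fixture(scope="session")
def default_corpus(tmp_path_factory) -> Corpus:
    """The shipped default corpus configuration."""
    return Corpus(tmp_path_factory.mktemp("default_corpus"),
                  simdata.default_profiles(), seed=42)


@pytest.fixture(scope="session")
def degenerate_corpus(tmp_path_factory) -> Corpus:
    return Corpus(tmp_path_factory.mktemp("degenerate_corpus"),
                  [degenerate_profile()], seed=5, block_records=2)


def make_record(accession: str = "GCF_000000001.1", taxid: int = 9606,
                total_length: int = 4000, lineage=("Bacteria",),
                n_exons: int = 0, year: int = 2017,
                assembler: str = "SPAdes") -> GenomeRecord:
    """Hand-built valid record for unit tests."""
    features = [FeatureRec(seqid="chr1", source="test", ftype="gene",
                           start=11, end=110, strand="+",
                           attributes=[AttributeRec("ID", "gene0")])]
    for i in range(n_exons):
        features.append(FeatureRec(
            seqid="chr1", source="test", ftype="exon",
            start=11 + 10 * i, end=20 + 10 * i, strand="+",
            attributes=[AttributeRec("ID", f"exon{i}"),
                        AttributeRec("Parent", "gene0")],
            parent="gene0"))
    return GenomeRecord(
        refseq_accession=accession, taxid=taxid, organism_name="Testus examplus",
        lineage=list(lineage), release_year=year,
        assembly=AssemblyMeta(
            assemblers=[AssemblerRec(assembler, "v. 1.0")],
            total_length=total_length, total_gap_length=total_length // 100,
            scaffold_n50=total_length // 2, scaffold_count=3,
            contig_n50=total_length // 4, contig_count=5),
        sequences=[SequenceRec(header="chr1", accession="chr1", length=0,
                               features=features)],
    )


def assert_tables_close(actual, expected, rel: float = 1e-9) -> None:
    """Row-by-row equality: exact for ints/strings/tuples, 1e-9 for floats."""
    assert len(actual.rows) == len(expected.rows), (
        f"{len(actual.rows)} rows vs {len(expected.rows)}")
    for ra, rb in zip(actual.rows, expected.rows):
        assert (ra.name, ra.indices) == (rb.name, rb.indices), (ra, rb)
        va, vb = ra.value, rb.value
        if isinstance(va, float) and isinstance(vb, float):
            assert math.isclose(va, vb, rel_tol=rel, abs_tol=rel), (ra, rb)
        else:
            assert va == vb, (ra, rb)
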