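"""Corpus generator: exact truth, determinism, and oracle summaries."""

import io
import math
import os

import pandas as pd
import pytest

from genoquery import simdata
from genoquery.ingest import parse_gff3

from conftest import degenerate_profile, light_profiles


def _count_ftypes(gff_path):
    with open(gff_path) as fh:
        mapping = parse_gff3(fh)
    counts = {}
    for feats in mapping.values():
        for f in feats:
            counts[f.ftype] = counts.get(f.ftype, 0) + 1
    return counts


def test_degenerate_profile_counts_are_exact(degenerate_corpus):
    """log-sd 0 and dispersion 0 pin 10 genes and 2 exons/gene exactly."""
    truth = degenerate_corpus.truth
    assert len(truth) == 5
    assert (truth.gene_count == 10).all()
    assert (truth.exon_count == 20).all()
    assert (truth.mean_gene_length == 1000.0).all()
    for gff in degenerate_corpus.gff_paths():
        assert _count_ftypes(gff) == {"gene": 10, "exon": 20}


def test_prokaryote_profile_emits_no_exons(tmp_path):
    profile = degenerate_profile(n_genomes=3)
    profile.has_exons = False
    _, truth = simdata.simulate_corpus([profile], seed=9, out_dir=tmp_path)
    assert (truth.exon_count == 0).all()
    for root, _dirs, files in os.walk(tmp_path):
        for f in files:
            if f.endswith(".gff"):
                assert "exon" not in _count_ftypes(os.path.join(root, f))


def test_same_seed_is_byte_identical(tmp_path):
    profiles = [degenerate_profile(n_genomes=2)]
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simdata.simulate_corpus(profiles, seed=77, out_dir=d1)
    simdata.simulate_corpus(profiles, seed=77, out_dir=d2)
    for root, _dirs, files in os.walk(d1):
        for name in files:
            p1 = os.path.join(root, name)
            p2 = os.path.join(str(d2), os.path.relpath(p1, str(d1)))
            assert open(p1, "rb").read() == open(p2, "rb").read(), p1


def test_different_seed_differs(tmp_path):
    profiles = light_profiles()
    for p in profiles:
        p.n_genomes = 3
    _, t1 = simdata.simulate_corpus(profiles, seed=1, out_dir=tmp_path / "a")
    _, t2 = simdata.simulate_corpus(profiles, seed=2, out_dir=tmp_path / "b")
    assert not t1.equals(t2)


def test_profile_validation_rejects_bad_weights():
    profile = degenerate_profile()
    profile.year_weights = {2018: 0.7}
    with pytest.raises(ValueError, match="year_weights"):
        simdata.simulate_corpus([profile], seed=1, out_dir="/tmp/unused")


def test_truth_matches_emitted_gff_for_random_profiles(tmp_path):
    profiles = light_profiles()
    for p in profiles:
        p.n_genomes = 4
    _, truth = simdata.simulate_corpus(profiles, seed=31, out_dir=tmp_path)
    for row in truth.itertuples():
        gff = os.path.join(tmp_path, "genomes", row.accession,
                           f"{row.accession}_genomic.gff")
        counts = _count_ftypes(gff)
        assert counts.get("gene", 0) == row.gene_count
        assert counts.get("exon", 0) == row.exon_count


def _toy_truth():
    rows = []
    for i, (year, genes, exons) in enumerate([
            (2015, 10, 20), (2015, 10, 30), (2016, 10, 20), (2018, 20, 40)]):
        rows.append(dict(
            accession=f"GCF_{i}", clade_name="Testa", lineage="Eukaryota;Testa",
            release_year=year, assembler_name="SPAdes", gene_count=genes,
            exon_count=exons, mean_gene_length=1000.0, total_length=10_000,
            total_gap_length=100, scaffold_count=5, scaffold_n50=4000,
            contig_count=8, contig_n50=2000))
    # a zero-exon prokaryote in 2016
    rows.append(dict(
        accession="GCF_p", clade_name="Bacteria", lineage="Bacteria",
        release_year=2016, assembler_name="SPAdes", gene_count=30,
        exon_count=0, mean_gene_length=900.0, total_length=4_000_000,
        total_gap_length=0, scaffold_count=1, scaffold_n50=4_000_000,
        contig_count=1, contig_n50=4_000_000))
    return pd.DataFrame(rows)


def test_expected_summaries_year_bucket_boundary():
    """2015 falls only in lt2016; 2016 only in ge2016."""
    tables = simdata.expected_summaries(_toy_truth())
    exon = tables["exon_stats"].set_index(["clade", "bucket"])
    assert exon.loc[("Testa", "lt2016"), "species"] == 2
    assert exon.loc[("Testa", "ge2016"), "species"] == 2
    assert ("Testa", "2015") not in exon.index
    assert exon.loc[("Testa", "lt2016"), "exons_per_gene_mean"] == pytest.approx(2.5)
    assert exon.loc[("Testa", "lt2016"), "exons_per_gene_sd"] == pytest.approx(
        math.sqrt(((2.0 - 2.5) ** 2 + (3.0 - 2.5) ** 2) / 1))


def test_expected_summaries_excludes_zero_exon_genomes_from_exon_means():
    tables = simdata.expected_summaries(_toy_truth())
    exon = tables["exon_stats"].set_index(["clade", "bucket"])
    row = exon.loc[("Bacteria", "ge2016")]
    assert row["species"] == 1
    assert row["n_with_exons"] == 0
    assert math.isnan(row["exon_number_mean"])
    assert row["gene_number_mean"] == 30


def test_expected_summaries_species_counts_partition(light_corpus):
    tables = simdata.expected_summaries(light_corpus.truth)
    exon = tables["exon_stats"]
    by_clade = exon.groupby("clade")["species"].sum()
    truth_counts = light_corpus.truth["clade_name"].value_counts()
    for clade, n in truth_counts.items():
        assert by_clade[clade] == n
    # assembler-year counts also partition the corpus per clade
    yc = tables["assembler_year_counts"]
    for clade, n in truth_counts.items():
        assert yc[yc["clade"] == clade]["genomes"].sum() == n


def test_load_profiles_from_config_text(tmp_path):
    cfg = tmp_path / "sim.cfg"
    cfg.write_text(
        "[clade:Bacteria]\n"
        "lineage = Bacteria\n"
        "n_genomes = 4\n"
        "has_exons = false\n"
        "gene_count_log_mean = 3.0\n"
        "year_weights = 2014:0.5, 2017:0.5\n"
        "assembler_weights_lt2016 = Newbler:1.0\n"
        "assembler_weights_ge2016 = SPAdes:0.5, CLC:0.5\n")
    profiles = simdata.load_profiles(cfg)
    assert len(profiles) == 1
    p = profiles[0]
    assert (p.clade_name, p.n_genomes, p.has_exons) == ("Bacteria", 4, False)
    assert p.year_weights == {2014: 0.5, 2017: 0.5}
    assert p.assembler_weights_ge2016 == {"SPAdes": 0.5, "CLC": 0.5}
    _, truth = simdata.simulate_corpus(profiles, seed=3, out_dir=tmp_path / "c")
    assert len(truth) == 4


def test_gff3_writer_output_reparses(degenerate_corpus):
    for gff in degenerate_corpus.gff_paths():
        with open(gff) as fh:
            mapping = parse_gff3(fh)
        buf = io.StringIO()
        simdata.write_gff3([f for feats in mapping.values() for f in feats], buf)
        assert parse_gff3(io.StringIO(buf.getvalue())) == mapping
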