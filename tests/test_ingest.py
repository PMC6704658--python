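"""File-format parsers: GFF3/GFF2, assembly stats/report, FASTA, assembly."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from genoquery import ingest, simdata
from genoquery.ingest import (
    AssemblyHeaderMeta, IngestError, build_genome_record, parse_assembly_report,
    parse_assembly_stats, parse_gff3, read_fasta,
)
from genoquery.schema import AttributeRec, FeatureRec

GFF_FIXTURE = """\
##gff-version 3
# a comment
chr1\tRefSeq\tgene\t100\t500\t.\t+\t.\tID=gene0;gbkey=Gene
chr1\tRefSeq\tmRNA\t100\t500\t.\t+\t.\tID=rna0;Parent=gene0
chr1\tRefSeq\texon\t100\t200\t0.9\t+\t.\tID=exon1;Parent=rna0
"""


def test_parse_gff3_fixture_order_and_fields():
    mapping = parse_gff3(io.StringIO(GFF_FIXTURE))
    assert list(mapping) == ["chr1"]
    feats = mapping["chr1"]
    assert [f.ftype for f in feats] == ["gene", "mRNA", "exon"]
    exon = feats[2]
    assert (exon.start, exon.end, exon.score, exon.strand) == (100, 200, 0.9, "+")
    assert exon.attributes == [AttributeRec("ID", "exon1"), AttributeRec("Parent", "rna0")]
    assert exon.parent == "rna0"
    assert feats[0].parent is None


def test_parse_gff3_empty_input():
    assert parse_gff3(io.StringIO("")) == {}


def test_parse_gff3_stops_at_fasta_section():
    text = GFF_FIXTURE + "##FASTA\n>chr1\nACGT\n"
    mapping = parse_gff3(io.StringIO(text))
    assert len(mapping["chr1"]) == 3


@pytest.mark.parametrize("line, fragment", [
    ("chr1\tx\tgene\t1\t10\t.\t+\t.", "9 tab-separated columns"),
    ("chr1\tx\tgene\tone\t10\t.\t+\t.\tID=a", "non-integer start/end"),
])
def test_parse_gff3_malformed_line_names_line_number(line, fragment):
    with pytest.raises(IngestError, match="line 2"):
        parse_gff3(io.StringIO("# header\n" + line + "\n"))
    with pytest.raises(IngestError, match=fragment):
        parse_gff3(io.StringIO("# header\n" + line + "\n"))


def test_percent_encoded_semicolon_does_not_split_attribute():
    line = "chr1\tx\tgene\t1\t10\t.\t+\t.\tNote=a%3Bb;ID=g1\n"
    feats = parse_gff3(io.StringIO(line))["chr1"]
    assert feats[0].attributes == [AttributeRec("Note", "a;b"), AttributeRec("ID", "g1")]


def test_gff2_space_separated_attributes():
    line = 'chr1\tx\texon\t1\t10\t.\t+\t.\tgene_id "abc"; transcript_id "xyz"\n'
    feats = parse_gff3(io.StringIO(line))["chr1"]
    assert feats[0].attributes == [AttributeRec("gene_id", "abc"),
                                   AttributeRec("transcript_id", "xyz")]


STATS_FIXTURE = """\
# Assembly Statistics Report
# unit-name\tmolecule-name\trefseq-accn\tstatistic\tvalue
all\tall\tall\ttotal-length\t4000
all\tall\tall\tcontig-count\t3
all\tall\tall\tcontig-N50\t2000
chr1\tall\tall\ttotal-length\t9999
"""


def test_parse_assembly_stats_reads_all_all_all_rows_only():
    meta = parse_assembly_stats(io.StringIO(STATS_FIXTURE))
    assert (meta.total_length, meta.contig_count, meta.contig_n50) == (4000, 3, 2000)
    assert (meta.scaffold_n50, meta.scaffold_count, meta.total_gap_length) == (0, 0, 0)


def test_parse_assembly_stats_scaffold_n50_row():
    text = "all\tall\tall\tscaffold-N50\t877000\n"
    assert parse_assembly_stats(io.StringIO(text)).scaffold_n50 == 877000


def test_parse_assembly_stats_header_only_is_rejected():
    with pytest.raises(IngestError, match="not an assembly stats file"):
        parse_assembly_stats(io.StringIO("# only comments\n"))


REPORT_FIXTURE = """\
# Assembly name:  ASM1v1
# Organism name:  Orycteropus afer afer (aardvark)
# Taxid:          1230840
# Date:           2016-03-14
# Assembly method: SOAPdenovo v. 2.04; AllPaths v. 41070
"""


def test_parse_assembly_report_fields():
    meta = parse_assembly_report(io.StringIO(REPORT_FIXTURE))
    assert meta.assembler_names == ["SOAPdenovo", "AllPaths"]
    assert meta.assembler_descs == ["v. 2.04", "v. 41070"]
    assert meta.date_year == 2016
    assert meta.taxid == 1230840
    assert meta.organism_name.startswith("Orycteropus")


def test_parse_assembly_report_without_headers_is_empty():
    meta = parse_assembly_report(io.StringIO("plain line\n# Random: x\n"))
    assert meta == AssemblyHeaderMeta()


def test_read_fasta_wrapped_and_ordered():
    pairs = read_fasta(io.StringIO(">s1\nacgt\nACGT\n>s2 description\nNNNN\n"))
    assert pairs == [("s1", "ACGTACGT"), ("s2 description", "NNNN")]
    assert read_fasta(io.StringIO("")) == []


def test_read_fasta_data_before_header_is_rejected():
    with pytest.raises(IngestError, match="before any FASTA header"):
        read_fasta(io.StringIO("ACGT\n>s1\nACGT\n"))


def test_build_genome_record_composes_parsers():
    gff = parse_gff3(io.StringIO(GFF_FIXTURE))
    stats = parse_assembly_stats(io.StringIO(STATS_FIXTURE))
    header = parse_assembly_report(io.StringIO(REPORT_FIXTURE))
    record = build_genome_record(gff, stats, header, lineage=["Bacteria"],
                                 accession="GCF_000000001.1")
    assert len(record.sequences) == 1
    assert len(record.sequences[0].features) == 3
    assert [a.name for a in record.assembly.assemblers] == ["SOAPdenovo", "AllPaths"]
    assert record.release_year == 2016
    assert record.lineage == ["Bacteria"]
    assert record.sequences[0].seq is None and record.sequences[0].length == 0


def test_build_genome_record_rejects_duplicate_fasta_seqid():
    with pytest.raises(IngestError, match="duplicate seqid"):
        build_genome_record({}, parse_assembly_stats(io.StringIO(STATS_FIXTURE)),
                            AssemblyHeaderMeta(),
                            fasta_pairs=[("s1", "ACGT"), ("s1", "GGCC")],
                            lineage=["Bacteria"], accession="GCF_1.1")


_tag = st.text(alphabet=st.characters(min_codepoint=33, max_codepoint=126,
                                      exclude_characters=";=,&%"), min_size=1, max_size=8)
_value = st.text(alphabet=st.characters(min_codepoint=32, max_codepoint=126),
                 min_size=0, max_size=12)


@st.composite
def feature_recs(draw):
    start = draw(st.integers(min_value=1, max_value=10_000))
    length = draw(st.integers(min_value=1, max_value=5_000))
    attrs = [AttributeRec(t, v) for t, v in
             draw(st.lists(st.tuples(_tag, _value), max_size=4))]
    parent = next((a.value for a in attrs if a.tag == "Parent"), None)
    return FeatureRec(
        seqid=draw(st.sampled_from(["chr1", "scaffold_2"])),
        source=draw(st.sampled_from(["RefSeq", "sim"])),
        ftype=draw(st.sampled_from(["gene", "exon", "mRNA", "CDS"])),
        start=start, end=start + length - 1,
        score=draw(st.one_of(st.none(), st.floats(allow_nan=False,
                                                  allow_infinity=False, width=32))),
        strand=draw(st.sampled_from(["+", "-", ".", "?"])),
        phase=draw(st.one_of(st.none(), st.integers(min_value=0, max_value=2))),
        attributes=attrs, parent=parent)


@given(st.lists(feature_recs(), min_size=1, max_size=10))
@settings(max_examples=60, derandomize=True, deadline=None)
def test_gff3_writer_parser_round_trip(features):
    """write_gff3 then parse_gff3 reproduces each FeatureRec exactly."""
    buf = io.StringIO()
    simdata.write_gff3(features, buf)
    parsed = parse_gff3(io.StringIO(buf.getvalue()))
    # grouping by seqid preserves within-seqid file order
    for seqid in {f.seqid for f in features}:
        assert parsed[seqid] == [f for f in features if f.seqid == seqid]
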