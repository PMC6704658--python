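# Per clade x year-bucket gene/exon statistics.
# Indexed by every clade on the genome's lineage and by the 2016 year
# boundary ("ge2016" / "lt2016"). Genomes with no genes stay in the species
# count but are excluded from gene-length and exons-per-gene means; genomes
# with no exons (prokaryotes) are excluded from the exon means.
g: Genome = input;
species: output sum[string][string] of int;
gene_number: output mean[string][string] of float;
gene_number_sd: output stdev[string][string] of float;
exon_number: output mean[string][string] of float;
exon_number_sd: output stdev[string][string] of float;
gene_length: output mean[string][string] of float;
gene_length_sd: output stdev[string][string] of float;
exons_per_gene: output mean[string][string] of float;
exons_per_gene_sd: output stdev[string][string] of float;
genes: int = 0;
exons: int = 0;
span_total: int = 0;
foreach (s: Sequence in g.sequences) {
    foreach (f: Feature in s.features) {
        if (f.ftype == "gene") {
            genes = genes + 1;
            span_total = span_total + (f.end - f.start + 1);
        }
        if (f.ftype == "exon") {
            exons = exons + 1;
        }
    }
}
bucket: string = "lt2016";
if (g.release_year >= 2016) {
    bucket = "ge2016";
}
foreach (c: string in g.lineage) {
    emit species[c][bucket] << 1;
    emit gene_number[c][bucket] << float(genes);
    emit gene_number_sd[c][bucket] << float(genes);
    if (genes > 0) {
        emit gene_length[c][bucket] << float(span_total) / float(genes);
        emit gene_length_sd[c][bucket] << float(span_total) / float(genes);
    }
    if (exons > 0) {
        emit exon_number[c][bucket] << float(exons);
        emit exon_number_sd[c][bucket] << float(exons);
        if (genes > 0) {
            emit exons_per_gene[c][bucket] << float(exons) / float(genes);
            emit exons_per_gene_sd[c][bucket] << float(exons) / float(genes);
        }
    }
}
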