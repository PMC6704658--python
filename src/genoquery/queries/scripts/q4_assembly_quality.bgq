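# Metazoan assembly quality per assembler, before and after 2016:
# mean +/- sample sd of total length, scaffold/contig counts and N50s,
# indexed [assembler name][year bucket].
g: Genome = input;
species: output sum[string][string] of int;
total_length: output mean[string][string] of float;
total_length_sd: output stdev[string][string] of float;
scaffold_count: output mean[string][string] of float;
scaffold_count_sd: output stdev[string][string] of float;
scaffold_n50: output mean[string][string] of float;
scaffold_n50_sd: output stdev[string][string] of float;
contig_count: output mean[string][string] of float;
contig_count_sd: output stdev[string][string] of float;
contig_n50: output mean[string][string] of float;
contig_n50_sd: output stdev[string][string] of float;
if (list_contains(g.lineage, "Metazoa")) {
    bucket: string = "lt2016";
    if (g.release_year >= 2016) {
        bucket = "ge2016";
    }
    foreach (a: Assembler in g.assembly.assemblers) {
        emit species[a.name][bucket] << 1;
        emit total_length[a.name][bucket] << float(g.assembly.total_length);
        emit total_length_sd[a.name][bucket] << float(g.assembly.total_length);
        emit scaffold_count[a.name][bucket] << float(g.assembly.scaffold_count);
        emit scaffold_count_sd[a.name][bucket] << float(g.assembly.scaffold_count);
        emit scaffold_n50[a.name][bucket] << float(g.assembly.scaffold_n50);
        emit scaffold_n50_sd[a.name][bucket] << float(g.assembly.scaffold_n50);
        emit contig_count[a.name][bucket] << float(g.assembly.contig_count);
        emit contig_count_sd[a.name][bucket] << float(g.assembly.contig_count);
        emit contig_n50[a.name][bucket] << float(g.assembly.contig_n50);
        emit contig_n50_sd[a.name][bucket] << float(g.assembly.contig_n50);
    }
}
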