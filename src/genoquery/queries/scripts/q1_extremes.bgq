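# Largest and smallest genome by assembly total length.
g: Genome = input;
max_genome: output maximum of string weight float;
min_genome: output minimum of string weight float;
emit max_genome << g.refseq_accession weight float(g.assembly.total_length);
emit min_genome << g.refseq_accession weight float(g.assembly.total_length);
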