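# Bacterial assembly-program popularity over time: genome counts per
# assembler per year, plus the top five assemblers within each year.
g: Genome = input;
assembler_year: output sum[string][int] of int;
top_assemblers: output top(5)[int] of string;
if (list_contains(g.lineage, "Bacteria")) {
    foreach (a: Assembler in g.assembly.assemblers) {
        emit assembler_year[a.name][g.release_year] << 1;
        emit top_assemblers[g.release_year] << a.name;
    }
}
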