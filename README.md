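# genoquery

A desk-scale data-science stack for genome **annotation and assembly
metadata**: a small typed query language, a compact binary record store, and
a map-reduce aggregation engine, plus a synthetic corpus generator so the
whole system is testable without downloading anything.

It is aimed at the situation where you have hundreds-to-thousands of genome
deposits — GFF3 annotation, NCBI `*_assembly_stats.txt` /
`*_assembly_report.txt` metadata, optionally FASTA — and want corpus-wide
answers ("how many exons per gene in fungi before vs after 2016?", "which
assembler dominates recent bacterial deposits?") without writing a new
throwaway script for each question.

## The model

Each genome is one record

```
Genome { refseq_accession, taxid, organism_name, lineage[], release_year,
         assembly { assemblers[], total_length, total_gap_length,
                    scaffold_count, scaffold_n50, contig_count, contig_n50 },
         sequences[] { header, length, features[] (GFF3 lines), seq? } }
```

and a query is a short script in a Sawzall-style language: it declares
**output aggregators**, then runs once per genome and `emit`s values into
them. Indices on an aggregator act as GROUP BY keys.

```
g: Genome = input;
max_genome: output maximum of string weight float;
min_genome: output minimum of string weight float;
emit max_genome << g.refseq_accession weight float(g.assembly.total_length);
emit min_genome << g.refseq_accession weight float(g.assembly.total_length);
```

Aggregators: `sum`, `mean`, `stdev` (sample, n−1), `maximum`/`minimum`
(weighted extremes), `top(k)` (exact frequency ranking). Execution is
map-reduce shaped: records are processed in chunks (one per store block),
each chunk folds emissions into mergeable partial states, and states merge
in ascending chunk order — so results are bit-identical for any worker
count. Assembly statistics follow the standard definitions: N50 is the
largest length L such that sequences ≥ L cover at least half the assembly;
contigs are scaffold segments split at runs of ≥ 10 `N`.

## Worked example

```
genoquery simulate --seed 42 --out corpus/          # 240-genome default corpus
genoquery build --manifest corpus/manifest.tsv --out corpus/db.bgsf
genoquery canonical q1 --db corpus/db.bgsf --out q1.tsv
cat q1.tsv
```

prints (seed 42):

```
max_genome = GCF_900000215.1, 4773717236.0
min_genome = GCF_900000082.1, 1528792.0
```

i.e. the largest simulated genome is a 4.8 Gbp metazoan deposit and the
smallest a 1.5 Mbp bacterium — each row is the accession plus the weight
(assembly total length in bp) it won with. The other canonical analyses:
`q2` gene/exon statistics per clade × year bucket, `q3` bacterial assembler
popularity per year, `q4` metazoan assembly quality per assembler before/
after 2016. `genoquery query your.bgq --db ... --workers 4 --out ...` runs
any script you write; `export-json`, `stats`, and `inspect` cover JSONL
export, FASTA-derived assembly statistics, and store debugging.

Library use mirrors the CLI: `simdata.simulate_corpus` →
`ingest.ingest_manifest` → `store.write_store` → `dsl.compile_source` →
`engine.run_query`.

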