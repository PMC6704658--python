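# Methods

This note records how genoquery computes what it computes: the execution
model, the numeric and formatting conventions that were pinned for
determinism, what the synthetic corpus emulates (and does not), and the
design choices that were genuinely open.

## Query execution model

A query script declares output aggregators and a per-genome body. The
compiler (hand-written lexer → recursive-descent parser → type checker →
closure compiler, in `genoquery.dsl`) produces a *pure* per-record
function: applied to one genome record it returns a list of emissions
`(output, index tuple, value, weight?)` and touches no state outside its
own environment. That purity is what makes map-side parallelism trivial and
is checked by tests (deep equality of the record before/after, identical
emission lists on repeated application).

The engine processes the store one block per chunk. Each chunk folds its
emissions into mergeable partial states; chunk states merge in **ascending
chunk order**, then finalize. Because merge order is fixed, floating-point
results are bit-identical for 1, 2, 4 or 8 workers (workers only change who
evaluates a chunk, never the merge tree). Aggregator state algebra:

| kind | state | update | merge |
|---|---|---|---|
| sum | total | add | add |
| mean | (n, Σx) | increment/add | add |
| stdev | (n, mean, M2) | Welford online | pairwise: M2 = M2a + M2b + δ²·na·nb/n |
| maximum/minimum | (value, weight) | keep strictly better weight; tie → lexicographically smaller value | re-apply rule |
| top(k) | value → count | increment | add counts |

`stdev` finalizes as the **sample** standard deviation √(M2/(n−1)), 0 when
n < 2 (the spread columns in the canonical outputs are “mean ± sample sd”;
a population sd would differ by √((n−1)/n)). `mean`/`stdev` outputs that
receive no emissions at all finalize as a single `n=0` marker row.
`top(k)` is exact counting — a desk-scale corpus fits in memory, so no
sketching is needed — with ties broken by value ascending. Rows are sorted
by (output name, index tuple); floats render via Python `repr`, the
shortest round-trip decimal.

Language semantics pinned for reproducibility: `int/int` division
truncates toward zero (C semantics, not Python floor), `%` is the matching
truncated remainder, mixed int/float arithmetic promotes to float, and an
int emitted into a float-declared output promotes at emission time. Weights
are required on `maximum`/`minimum` (they are the comparison key) and
rejected on the other aggregators. Absent optional schema fields read as
`score → 0.0`, `phase → −1`, `parent → ""`, `seq → ""`.

## Record store

Records serialize with a canonical tag-length-value codec (field-id tables
documented in `genoquery/store.py`): fields in ascending field-id order,
varints for non-negative integers, length-delimited UTF-8 for strings and
nested records, a 64-bit LE double for feature scores, absent optionals
omitted. Equal records therefore produce byte-identical encodings, and
unknown field ids are skipped by wire type on decode. The store file is a
5-byte magic + flags + u64 record count, then blocks of 256 records
(default), each DEFLATE-compressed with records varint-length-prefixed
inside the block — the length prefix is what makes the concatenation
self-delimiting. DEFLATE at level 6 is the single mandated codec so that
identical inputs give byte-identical files across runs and machines.

## Assembly statistics

N50 uses exact integer arithmetic (`2·cumulative ≥ total`) to avoid float
edge cases. Contigs are scaffold segments split at maximal runs of ≥ 10
`N` (the common convention for NCBI-style gap calling); shorter N runs stay
inside contigs, and `total-gap-length` counts only the splitting runs — the
stats writer documents this, since counting *all* ambiguous bases is a
defensible alternative convention.

## Synthetic corpus

`genoquery.simdata` emulates the per-genome metadata structure of a RefSeq
snapshot: clade lineage, submission year, assembler program (with a mixture
shift at the 2016 boundary), per-genome gene count, per-gene length and
exon count, and assembly statistics (scaffold lengths via a Dirichlet split
of the genome length, Poisson gap counts per scaffold).

* Gene counts, gene lengths, genome lengths and scaffold counts are
  lognormal; a log-sd of 0 degenerates to an exact value, which the
  exactness tests exploit (10 genes × 2 exons → exons-per-gene 2.0 ± 0.0).
* Exons per gene is a shifted negative binomial (min 1, stated mean and
  dispersion); dispersion ≤ 0 degenerates to the rounded mean. Prokaryote
  profiles emit no exon features at all.
* Genes are laid out left to right with 100 bp spacers, strands
  alternating; exons tile the gene span. Coordinates are GFF3: 1-based,
  inclusive; gene length = end − start + 1.

The default configuration keeps the *relative* structure of real clades —
metazoan exons-per-gene ≈ 17.7, fungal ≈ 2.9, plant ≈ 9.2, bacterial gene
length ≈ 890 bp, genome lengths from Mbp (bacteria) to Gbp (metazoa) — but
scales per-genome gene counts down by roughly two orders of magnitude
(e.g. bacteria ~43 genes instead of ~4.3k) so the 240-genome corpus
simulates, ingests and queries in well under a minute. The corpus does
**not** emulate: realistic sequence content (FASTA emission is optional,
filler residues), overlapping or nested gene models, UTR/CDS phase
bookkeeping, pseudogenes, taxonomy-tree structure beyond a fixed lineage
list, or correlations between assembly quality and year. Passing tests
therefore demonstrate the *machinery* (parsing, codec, aggregation
algebra, grouping, determinism) on realistically shaped metadata — not
biological conclusions about real RefSeq.

“Exons per gene” is the per-genome ratio (total exons / total genes),
averaged across genomes with ± sample sd; a pooled ratio across the clade
would weight large genomes more. “Gene length” is likewise the per-genome
mean span. Year buckets are `year ≥ 2016` vs `year < 2016`. Genomes with
zero genes stay in species counts but are excluded from gene-length and
exons-per-gene means; genomes with zero exons are excluded from exon-number
and exons-per-gene means (prokaryote clades thus report no exon rows rather
than rows of zeros).

Clade membership is an exact, case-sensitive lineage-containment test, and
query outputs index by every clade on the lineage — so one genome appears
under `Eukaryota`, `Fungi` and `Ascomycota` alike, mirroring how clade
summary tables usually double-list nested clades.

## Verification strategy and problem sizes

Every aggregate the engine produces is cross-checked against an
independent path: brute-force single-pass oracles for the aggregator
algebra (200 random emission lists per kind; exact for the discrete kinds,
1e-9 for mean/stdev — relative for large-magnitude assembly statistics),
a direct-iteration oracle for each canonical query (no DSL, no engine),
and the generator's truth table for pipeline identity. Parameter recovery
runs the full simulate→ingest→store→query chain at 200 genomes per clade
over five fixed seeds and requires the engine-computed mean gene count to
land within 3 standard errors of the generating lognormal mean. The test
corpus for worker-equivalence uses 1,000 genomes across three clades with
reduced gene counts; these sizes keep the suite under ~2 minutes while
still exercising multi-block stores and all grouping paths.

## Known limitations

* The DSL has no user-defined functions, regular expressions, or list
  literals; clade filters are `list_contains` on the lineage.
* `maximum`/`minimum` return one extreme per index (not n extremes).
* Assembler names are canonicalized only by trimming whitespace and
  stripping ` v. `/` version ` suffixes; `SPAdes` and `spades` remain
  distinct programs.
* The store supports no appends, concurrent writers, or schema evolution
  beyond skip-unknown-field.
* Gzip input is handled transparently, but all deliverable formats are
  plain text or the documented binary store.
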