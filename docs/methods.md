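# Methods

## Data model

A build maps a genome collection onto an integer matrix: rows are genomes in
manifest order, columns are features in first-seen order over the manifest
sweep. Two feature modes exist:

* **domain** — columns are version-stripped Pfam accessions; cell (g, f) is
  the total number of per-domain hits of f across all of g's proteins
  (a protein with two copies of a domain contributes 2).
* **architecture** — columns are whole domain-architecture strings; cell
  (g, f) is the number of g's proteins whose architecture equals f.

The count matrix is canonical on disk; the binary presence/absence view is
derived at load time by replacing every stored value with 1, never by
densifying.

## Parsing and architecture construction

Input files are hmmsearch per-domain tabular output (`--domtblout`), plain
or gzipped. Proteins are the search targets and Pfam profiles the queries;
we take the query accession (falling back to the query name when the
accession is `-`), truncate it at the first `.` so architecture strings use
unversioned accessions, and read the per-domain independent E-value, bit
score, and envelope coordinates. Envelope rather than alignment coordinates
order domains along the protein; since coordinates are used only for
within-protein ordering, any consistently chosen pair would do — the choice
is documented here so builds are reproducible. No E-value filter is applied
by default (every reported per-domain line counts); `--max-i-evalue`
enables one.

A protein's architecture is its accessions sorted by (start, end,
accession) ascending and joined with `_`. Ties on start break on end, then
lexicographically. Overlapping hits are kept as reported; tandem repeats are
kept, not collapsed (the TcdA toxin architecture legitimately contains
PF19127 five times). The `_` delimiter is load-bearing: accessions
containing `_`, `.` or whitespace are rejected at parse time so strings
always split back into their units.

## Compression

Construction streams one genome at a time, accumulating per-row
(column-index, count) pairs; the index-pointer array is the cumulative sum
of per-row nonzero counts. No dense intermediate is ever materialized, so
build memory is proportional to nonzeros plus the label indexes. Indices
and values are int64 throughout, so 10⁵-genome collections cannot overflow.
First-seen column order keeps the build single-pass and deterministic for a
fixed manifest.

Queries run directly on (P, C, V): the row id of each stored entry is
recovered with `repeat(arange(n_rows), diff(P))`, row/column subsets become
boolean masks, and sums/presence counts are `bincount` reductions — O(nnz)
per query.

## On-disk layout

A matrix folder holds `matrix.json` (format version 1, shape, nnz, binary
flag, mode), three flat little-endian int64 array files (`indptr.bin`,
`indices.bin`, `values.bin`), newline-delimited UTF-8 label files
(`rows.txt`, `cols.txt`), and — for keep-mode builds — `protein_ids.tsv`, a
deduplicated, lexicographically sorted (genome, feature, protein) store
backing protein-id retrieval, plus `keep.tsv`, the raw
(genome, protein, feature) associations in build order. Nothing in a folder
depends on wall-clock time, so identical inputs give byte-identical
folders; that determinism is asserted in the tests.

## Conservation cutoff semantics

`cal_core` operates on the binary matrix only; a count matrix is refused
rather than silently thresholded, so "present twice" can never count
double. A feature is core when its presence count over the queried genome
list satisfies `count / len(list_row) >= cutoff`, inclusive, with the
denominator taken from the query list (genomes with zero hits still count).
The comparison is exact-rational: the float cutoff is interpreted as the
decimal literal the user wrote (`Fraction(str(cutoff))`), because the
binary-float image of 0.95 is slightly *above* 19/20 and a naive float (or
even `Fraction(float)`) comparison would wrongly drop a feature present in
exactly 95% of genomes. Default cutoff: 0.95.

## Synthetic data

The fixture generator emulates the statistical shape of per-genome
hmmsearch results: each genome gets `Poisson(mean_proteins_per_genome)`
proteins; each protein carries hits with probability `presence_density`; a
hit protein gets `1 + Poisson(mean_domains_per_protein − 1)` sequential,
non-overlapping domain segments, each unit either tandem-repeating its
predecessor (probability `repeat_domain_prob`) or drawn uniformly from the
vocabulary. Defaults (20 genomes, 50-domain vocabulary, ~30 proteins per
genome, mean 1.5 domains per protein, 10% repeat probability, 0.9 presence
density) sketch a small bacterial pan-genome slice. The generator records
exact ground truth (dense count matrices, full association table) as it
writes the files, so builder output can be compared field-by-field.

What the generator does **not** emulate: real sequences or alignment
scores, Pfam's heavy-tailed domain frequency spectrum, correlated domain
co-occurrence, or genome-quality artifacts. Passing tests therefore
demonstrate the correctness of parsing, compression, serialization and
query algebra on realistic *shapes* of data — not biological conclusions
about real genome collections.

The dense brute-force oracle answers the same queries by exhaustive
pure-python iteration over the ground-truth dense matrix (the role a
relational store plays as a baseline); every compressed-path result is
required to equal it exactly.

## Numerical and design choices

* Row vectors handed to `compress_rows` must be sorted; unsorted or
  out-of-range input raises rather than being silently reordered.
* Empty genomes keep their (all-zero) rows: the index pointer is flat
  across them, and they count in conservation denominators.
* Label lookups are exact string matches; unknown labels raise naming the
  offending label rather than returning empty results.
* Protein-id reports are sorted (genome, feature, protein) and
  deduplicated, so a protein carrying the same domain twice appears once
  per (genome, feature) pair; the raw keep file retains every association.
* Scaling measurements use in-memory random binary matrices of
  100/1,000/10,000 genomes × 2,000 features at density 0.3, the smallest
  sizes at which per-call overhead (label resolution, result-frame
  construction) is negligible against the O(nnz) kernel; each timing is the
  best of five runs.

## Known limitations

* Only the hmmsearch per-domain tabular dialect is parsed; hmmscan and
  human-readable output are out of scope.
* No overlap resolution or clan-level deduplication of domain hits.
* The architecture matrix treats strings atomically; no similarity or
  edit-distance between architectures.
* Column order is manifest-dependent (first-seen), so matrices built from
  reordered manifests differ in layout (though not in content under label
  lookup).
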