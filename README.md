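# domatrix

Compressed sparse genome × protein-domain matrices for comparative-genomics
screening.

## The problem

Protein function can be abstracted as a set of Pfam functional domains, or —
when order matters — as a *domain architecture*: the domain accessions along
a protein joined by underscores (`PF01742_PF07952_PF07953_PF07951` is a
botulinum-neurotoxin-like protein). Mapping a genome collection onto a
matrix with one row per genome and one column per domain or architecture
turns questions like "is this domain part of the core genome?" or "which
genomes carry an exotoxin architecture?" into simple matrix queries. At
pan-genome scale (thousands to hundreds of thousands of genomes) that matrix
is enormous and almost entirely zeros, so `domatrix` stores it in compressed
sparse row (CSR) form:

1. **Coordinate transformation** — enumerate only the nonzero cells as
   parallel row/column/value vectors `(R, C, V)`, abolishing the zeros;
2. **Row compression** — replace the sorted row vector `R` by index pointers
   `P` of length `n_rows + 1`, where `P[i]:P[i+1]` slices row *i* out of
   `C` and `V`.

Memory is then `O(nnz)`, the matrix lives in local RAM, and every query
(row/column sums, core-feature calculation at a conservation cutoff,
protein-id retrieval) runs on the compressed arrays without densifying.

Input is what a standard annotation pipeline already produces: per-genome
`hmmsearch --domtblout` results against the Pfam profile library, listed in
a two-column manifest TSV of `(genome_id, result_path)`.

## Worked example

Build an architecture matrix from synthetic demo genomes (a
*C. difficile*-like genome with TcdA/TcdB toxin proteins, a *C. botulinum*-like
genome with a BoNT protein, an *E. coli*-like genome with RpoD):

```python
import tempfile
import domatrix
from domatrix import fixtures

tmp = tempfile.mkdtemp()
manifest = fixtures.write_toxin_demo(f"{tmp}/demo")
matrix = domatrix.build_architecture_matrix(manifest, keep=True)
print(matrix.get_columns())
print(matrix.get_protein_ids(list_col=[fixtures.BONT_ARCHITECTURE]))
```

prints

```
['PF12918_PF12919_PF11713_PF12920_PF19127_PF19127_PF19127_PF19127_PF19127', 'PF12918_PF12919_PF11713_PF12920_PF19127_PF19127', 'PF01742_PF07952_PF07953_PF07951', 'PF04542']
  genome_id                          feature protein_id
0      cbot  PF01742_PF07952_PF07953_PF07951  cbot_bont
```

— the first two columns are the TcdA (nine domain units, five tandem
PF19127 repeats) and TcdB (six units) architectures, and the protein-id
query pinpoints the one protein whose full architecture matches the
neurotoxin string.

The same flows from a shell:

```sh
domatrix build-domain -i manifest.tsv -o domain_matrix -k
domatrix core -m domain_matrix --cutoff 0.95
domatrix protein-ids -m domain_matrix --cols features.txt -o report.tsv
```

`core` reports, for each feature present in ≥95% (inclusive) of the queried
genomes, its genome count and conservation fraction. The cutoff comparison
is exact-rational, so a domain in exactly 19 of 20 genomes is core at 0.95.

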