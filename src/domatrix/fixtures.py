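"""Synthetic hmmsearch results with ground truth, plus a dense brute-force oracle.

Real inputs to a build are per-genome ``hmmsearch --domtblout`` files against
the Pfam library.  The generator here emulates their statistical shape — a
sparse genome x domain landscape with multi-domain proteins and occasional
tandem repeats — while recording exact ground truth (dense count matrices and
the full genome/protein/feature association table), so every other module is
testable without downloading anything.  It makes no attempt at biologically
realistic sequences, scores, or Pfam's true domain frequency spectrum.

Also here:

* :func:`naive_oracle` — answers core/sum/protein-id queries by exhaustive
  iteration over the dense truth, the reference the compressed path is
  checked against (a stand-in for a relational-store baseline).
* :func:`random_binary_matrix` — in-memory random presence/absence matrices
  for scaling experiments.
* Hand-written hit sets for the clostridial toxin and sigma-factor worked
  examples (TcdA, TcdB, BoNT, the sigma-70 region-2 domain PF04542).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hmmer_io import DomainHit, GenomeManifest, read_manifest
from .sparse_matrix import LabeledCSR, compress_rows

__all__ = [
    "FixtureSpec",
    "FixtureTruth",
    "generate_fixture",
    "write_domtblout",
    "naive_oracle",
    "random_binary_matrix",
    "toxin_demo_hits",
    "write_toxin_demo",
    "TCDB_ARCHITECTURE",
    "TCDA_ARCHITECTURE",
    "BONT_ARCHITECTURE",
    "SIGMA70_REGION2",
]

# Domain architectures of the clostridial toxins and the sigma-70 region-2
# domain used in the worked examples (UniProt-derived architecture strings).
TCDB_ARCHITECTURE = "PF12918_PF12919_PF11713_PF12920_PF19127_PF19127"
TCDA_ARCHITECTURE = (
    "PF12918_PF12919_PF11713_PF12920_PF19127_PF19127_PF19127_PF19127_PF19127"
)
BONT_ARCHITECTURE = "PF01742_PF07952_PF07953_PF07951"
SIGMA70_REGION2 = "PF04542"


# ---------------------------------------------------------------------------
# domtblout writing


def write_domtblout(path: str | Path, hits: Sequence[DomainHit]) -> None:
    """Write hits as hmmsearch per-domain tabular output.

    Whitespace-delimited with the standard 23 columns; numeric fields are
    written with ``repr`` so parsing recovers the exact float values.
    Columns not represented in :class:`DomainHit` get plausible filler.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# target name        accession   tlen query name           accession   qlen"
                 "   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to"
                 "  from    to  from    to  acc description of target\n#\n")
        for h in hits:
            tlen = h.ali_end + 25
            fields = [
                h.protein_id,            # target name (the protein)
                "-",                     # target accession
                str(tlen),               # tlen
                f"{h.domain_accession}_hmm",  # query name
                f"{h.domain_accession}.1",    # query accession (versioned)
                str(h.ali_end - h.ali_start + 1),  # qlen
                repr(h.i_evalue),        # full-sequence E-value (filler)
                repr(h.bit_score),       # full-sequence score (filler)
                "0.1",                   # bias
                "1", "1",                # dom #, of
                repr(h.i_evalue),        # c-Evalue (filler)
                repr(h.i_evalue),        # i-Evalue
                repr(h.bit_score),       # domain score
                "0.1",                   # domain bias
                "1", str(h.ali_end - h.ali_start + 1),  # hmm from/to
                str(h.ali_start), str(h.ali_end),       # ali from/to
                str(h.ali_start), str(h.ali_end),       # env from/to
                "0.95",                  # acc
                "synthetic",             # description
            ]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# random fixture generation


@dataclass(frozen=True)
class FixtureSpec:
    """Shape parameters of a synthetic genome set.

    Defaults sketch a small bacterial pan-genome slice: 20 genomes over a
    50-domain vocabulary, ~30 annotated proteins per genome, mostly
    single-domain proteins with occasional multi-domain ones and a 10%
    chance that a unit tandem-repeats its predecessor.
    """

    n_genomes: int = 20
    domain_vocab_size: int = 50
    mean_proteins_per_genome: float = 30.0
    mean_domains_per_protein: float = 1.5
    repeat_domain_prob: float = 0.1
    presence_density: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 0 or self.domain_vocab_size <= 0:
            raise ValueError("counts must be positive")
        if self.mean_proteins_per_genome < 0 or self.mean_domains_per_protein < 1:
            raise ValueError("mean_proteins_per_genome >= 0 and mean_domains_per_protein >= 1")
        for p in (self.repeat_domain_prob, self.presence_density):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class FixtureTruth:
    """Exact ground truth for a generated fixture.

    Dense count matrices with columns in first-seen order over the manifest
    sweep (the order the streaming builder also uses), plus the full
    association table of every generated hit.
    """

    genome_ids: list[str]
    domain_cols: list[str]
    domain_counts: np.ndarray
    arch_cols: list[str]
    arch_counts: np.ndarray
    # one row per generated hit: (genome_id, protein_id, domain, architecture)
    associations: pd.DataFrame = field(repr=False, default=None)

    def dense(self, mode: str, binary: bool = False) -> np.ndarray:
        counts = self.domain_counts if mode == "domain" else self.arch_counts
        return (counts > 0).astype(np.int64) if binary else counts

    def cols(self, mode: str) -> list[str]:
        return self.domain_cols if mode == "domain" else self.arch_cols


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> tuple[GenomeManifest, FixtureTruth]:
    """Write one domtblout file per genome plus a manifest; return exact truth.

    Deterministic for a fixed spec (seed included): rerunning produces
    byte-identical files.  Proteins carry hits with probability
    ``presence_density``; a hit protein gets ``1 + Poisson(mean - 1)``
    sequential non-overlapping domain segments, each unit either repeating
    its predecessor (tandem repeat) or drawn uniformly from the vocabulary.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    vocab = [f"PF{10000 + i:05d}" for i in range(spec.domain_vocab_size)]

    genome_ids = [f"g{i:05d}" for i in range(spec.n_genomes)]
    domain_col_idx: dict[str, int] = {}
    arch_col_idx: dict[str, int] = {}
    domain_rows: list[dict[int, int]] = []
    arch_rows: list[dict[int, int]] = []
    assoc_records: list[tuple[str, str, str, str]] = []

    manifest_lines = []
    for genome_id in genome_ids:
        hits: list[DomainHit] = []
        d_counts: dict[int, int] = {}
        a_counts: dict[int, int] = {}
        n_proteins = int(rng.poisson(spec.mean_proteins_per_genome))
        for p in range(n_proteins):
            protein_id = f"{genome_id}_p{p:04d}"
            if rng.random() >= spec.presence_density:
                continue
            n_units = 1 + int(rng.poisson(spec.mean_domains_per_protein - 1.0))
            cursor = int(rng.integers(1, 40))
            units: list[str] = []
            for _ in range(n_units):
                if units and rng.random() < spec.repeat_domain_prob:
                    acc = units[-1]
                else:
                    acc = vocab[int(rng.integers(0, len(vocab)))]
                length = int(rng.integers(60, 300))
                start, end = cursor, cursor + length - 1
                cursor = end + int(rng.integers(1, 50))
                units.append(acc)
                hits.append(
                    DomainHit(
                        protein_id=protein_id,
                        domain_accession=acc,
                        ali_start=start,
                        ali_end=end,
                        bit_score=round(float(rng.uniform(25.0, 900.0)), 1),
                        i_evalue=float(10.0 ** rng.uniform(-60.0, -1.0)),
                    )
                )
            arch = "_".join(units)
            for acc in units:
                j = domain_col_idx.setdefault(acc, len(domain_col_idx))
                d_counts[j] = d_counts.get(j, 0) + 1
                assoc_records.append((genome_id, protein_id, acc, arch))
            k = arch_col_idx.setdefault(arch, len(arch_col_idx))
            a_counts[k] = a_counts.get(k, 0) + 1
        domain_rows.append(d_counts)
        arch_rows.append(a_counts)
        hit_path = out_dir / f"{genome_id}.domtbl"
        write_domtblout(hit_path, hits)
        manifest_lines.append(f"{genome_id}\t{hit_path}")

    manifest_path = out_dir / "manifest.tsv"
    manifest_path.write_text("\n".join(manifest_lines) + ("\n" if manifest_lines else ""))

    def densify(rows: list[dict[int, int]], n_cols: int) -> np.ndarray:
        dense = np.zeros((spec.n_genomes, n_cols), dtype=np.int64)
        for i, counts in enumerate(rows):
            for j, v in counts.items():
                dense[i, j] = v
        return dense

    truth = FixtureTruth(
        genome_ids=genome_ids,
        domain_cols=list(domain_col_idx),
        domain_counts=densify(domain_rows, len(domain_col_idx)),
        arch_cols=list(arch_col_idx),
        arch_counts=densify(arch_rows, len(arch_col_idx)),
        associations=pd.DataFrame(
            assoc_records, columns=["genome_id", "protein_id", "domain", "architecture"]
        ),
    )
    return read_manifest(manifest_path), truth


# ---------------------------------------------------------------------------
# dense brute-force oracle


def naive_oracle(
    truth: FixtureTruth,
    query: str,
    mode: str = "domain",
    list_row: Sequence[str] | None = None,
    list_col: Sequence[str] | None = None,
    cutoff: float = 0.95,
    binary: bool = False,
) -> pd.DataFrame:
    """Answer a query by exhaustive iteration over the dense truth.

    ``query`` is one of ``core``, ``sum_rows``, ``sum_columns``,
    ``protein_ids``.  Pure-python loops over the dense matrix — slow on
    purpose; this is the reference the compressed path is validated (and
    timed) against.
    """
    rows = list(list_row) if list_row is not None else list(truth.genome_ids)
    cols = list(list_col) if list_col is not None else truth.cols(mode)
    dense = truth.dense(mode, binary=binary or query == "core")
    ri = {g: i for i, g in enumerate(truth.genome_ids)}
    ci = {f: j for j, f in enumerate(truth.cols(mode))}

    if query == "sum_rows":
        sums = []
        for g in rows:
            total = 0
            for f in cols:
                total += int(dense[ri[g], ci[f]])
            sums.append(total)
        return pd.DataFrame({"row_name": rows, "row_sum": np.asarray(sums, dtype=np.int64)})

    if query == "sum_columns":
        sums = []
        for f in cols:
            total = 0
            for g in rows:
                total += int(dense[ri[g], ci[f]])
            sums.append(total)
        return pd.DataFrame({"col_name": cols, "col_sum": np.asarray(sums, dtype=np.int64)})

    if query == "core":
        cut = Fraction(Decimal(str(cutoff)))
        names, counts, fracs = [], [], []
        for f in cols:
            present = 0
            for g in rows:
                if dense[ri[g], ci[f]] > 0:
                    present += 1
            if Fraction(present, len(rows)) >= cut:
                names.append(f)
                counts.append(present)
                fracs.append(present / len(rows))
        return pd.DataFrame(
            {
                "col_name": names,
                "genome_count": np.asarray(counts, dtype=np.int64),
                "fraction": np.asarray(fracs, dtype=np.float64),
            }
        )

    if query == "protein_ids":
        feat_col = "domain" if mode == "domain" else "architecture"
        out = set()
        for _, rec in truth.associations.iterrows():
            if rec["genome_id"] in rows and rec[feat_col] in cols:
                out.add((rec["genome_id"], rec[feat_col], rec["protein_id"]))
        return pd.DataFrame(
            sorted(out), columns=["genome_id", "feature", "protein_id"]
        )

    raise ValueError(f"unknown query: {query!r}")


# ---------------------------------------------------------------------------
# in-memory random matrices (scaling experiments)


def random_binary_matrix(
    n_genomes: int, n_features: int, density: float, rng: np.random.Generator
) -> tuple[LabeledCSR, np.ndarray]:
    """A random labeled presence/absence CSR matrix plus its dense mirror."""
    dense = rng.random((n_genomes, n_features)) < density
    row, col = np.nonzero(dense)
    matrix = LabeledCSR(
        indptr=compress_rows(row, n_genomes),
        indices=col.astype(np.int64),
        values=np.ones(len(col), dtype=np.int64),
        row_labels=[f"g{i:06d}" for i in range(n_genomes)],
        col_labels=[f"PF{j:05d}" for j in range(n_features)],
        is_binary=True,
    )
    return matrix, dense.astype(np.int64)


# ---------------------------------------------------------------------------
# worked-example fixtures (clostridial toxins, sigma-70 region 2)


def _sequential_hits(protein_id: str, accessions: Sequence[str]) -> list[DomainHit]:
    hits = []
    for i, acc in enumerate(accessions):
        start = 1 + 200 * i
        hits.append(
            DomainHit(
                protein_id=protein_id,
                domain_accession=acc,
                ali_start=start,
                ali_end=start + 150,
                bit_score=100.0 + 10.0 * i,
                i_evalue=1e-30,
            )
        )
    return hits


def toxin_demo_hits() -> dict[str, list[DomainHit]]:
    """Hand-built hit sets for three demo genomes.

    ``cdiff`` carries TcdA- and TcdB-like proteins (large clostridial
    toxins), ``cbot`` a botulinum-neurotoxin-like protein, and ``ecoli`` an
    RpoD-like protein with the sigma-70 region-2 domain.
    """
    return {
        "cdiff": (
            _sequential_hits("cdiff_tcdA", TCDA_ARCHITECTURE.split("_"))
            + _sequential_hits("cdiff_tcdB", TCDB_ARCHITECTURE.split("_"))
        ),
        "cbot": _sequential_hits("cbot_bont", BONT_ARCHITECTURE.split("_")),
        "ecoli": _sequential_hits("ecoli_rpoD", [SIGMA70_REGION2]),
    }


def write_toxin_demo(out_dir: str | Path) -> GenomeManifest:
    """Write the toxin/sigma demo genomes as domtblout files plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = []
    for genome_id, hits in toxin_demo_hits().items():
        path = out_dir / f"{genome_id}.domtbl"
        write_domtblout(path, hits)
        lines.append(f"{genome_id}\t{path}")
    manifest_path = out_dir / "manifest.tsv"
    manifest_path.write_text("\n".join(lines) + "\n")
    return read_manifest(manifest_path)
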