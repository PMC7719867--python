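"""Reading genome manifests and hmmsearch per-domain (domtblout) results.

The build input is a two-column tab-delimited manifest mapping unique genome
ids to the paths of their HMMER ``hmmsearch --domtblout`` result files.  Each
per-domain line of such a file becomes one :class:`DomainHit`: the protein
(the search target), the profile accession of the matching Pfam domain with
any ``.N`` version suffix stripped, the envelope coordinates on the protein,
and the per-domain score and independent E-value.
"""

from __future__ import annotations

import gzip
import io
import re
from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import HmmerParseError, ManifestError

__all__ = [
    "GenomeManifest",
    "DomainHit",
    "read_manifest",
    "parse_domain_hits",
    "hits_by_protein",
]

# Accession with no version suffix: letters/digits only after stripping at '.'
_ACCESSION_RE = re.compile(r"^[^.\s_]+$")


@dataclass(frozen=True)
class GenomeManifest:
    """Ordered (genome_id, path) pairs; order fixes downstream matrix row order."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for genome_id, _ in self.entries:
            if genome_id in seen:
                raise ManifestError(f"duplicate genome id in manifest: {genome_id!r}")
            seen.add(genome_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def genome_ids(self) -> list[str]:
        return [g for g, _ in self.entries]


@dataclass(frozen=True)
class DomainHit:
    """One per-domain match of a profile HMM against one protein.

    Coordinates are the envelope bounds, 1-based inclusive; they are used only
    to order domains along the protein.  ``domain_accession`` carries no
    version suffix (``PF04542``, never ``PF04542.12``).
    """

    protein_id: str
    domain_accession: str
    ali_start: int
    ali_end: int
    bit_score: float
    i_evalue: float

    def __post_init__(self) -> None:
        if self.ali_start > self.ali_end:
            raise HmmerParseError(
                f"hit on {self.protein_id!r}: ali_start {self.ali_start} > ali_end {self.ali_end}"
            )
        if self.i_evalue < 0:
            raise HmmerParseError(f"hit on {self.protein_id!r}: negative i-Evalue")
        if not _ACCESSION_RE.match(self.domain_accession):
            raise HmmerParseError(
                f"invalid domain accession {self.domain_accession!r} "
                "(must be version-stripped, no '.', '_' or whitespace)"
            )


def read_manifest(path: str | Path) -> GenomeManifest:
    """Read a two-column TSV of (genome_id, hmmsearch result path).

    ``#``-prefixed comment lines and blank lines are ignored.  Paths are not
    checked for existence here; they are validated when parsed.

    Raises
    ------
    ManifestError
        On a duplicate genome id or a line with fewer than two fields.
    """
    entries: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ManifestError(
                    f"{path}: line {lineno}: expected >=2 tab-separated fields, got {len(fields)}"
                )
            genome_id, hit_path = fields[0].strip(), fields[1].strip()
            if genome_id in seen:
                raise ManifestError(f"{path}: line {lineno}: duplicate genome id {genome_id!r}")
            seen.add(genome_id)
            entries.append((genome_id, hit_path))
    return GenomeManifest(tuple(entries))


def strip_accession_version(accession: str) -> str:
    """``PF04542.12`` -> ``PF04542`` (truncate at the first '.')."""
    return accession.split(".", 1)[0]


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, encoding="utf-8")


# domtblout per-domain columns (0-based) we consume.  Proteins are the search
# targets; the Pfam profile is the query.
_COL_TARGET_NAME = 0
_COL_QUERY_NAME = 3
_COL_QUERY_ACC = 4
_COL_I_EVALUE = 12
_COL_DOM_SCORE = 13
_COL_ENV_FROM = 19
_COL_ENV_TO = 20
_MIN_FIELDS = 21  # description column may be absent


def parse_domain_hits(
    path: str | Path, max_i_evalue: float | None = None
) -> list[DomainHit]:
    """Parse an hmmsearch ``--domtblout`` file into :class:`DomainHit` records.

    Plain or gzip-compressed (by ``.gz`` suffix) files are accepted.  Comment
    lines (leading ``#``) are skipped.  The Pfam accession is taken from the
    query-accession column (falling back to the query name when hmmsearch
    reports ``-``) and truncated at the first ``.``.  With ``max_i_evalue``
    set, per-domain lines whose independent E-value exceeds it are dropped;
    the default accepts every reported line.
    """
    hits: list[DomainHit] = []
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < _MIN_FIELDS:
                raise HmmerParseError(
                    f"{path}: line {lineno}: expected >={_MIN_FIELDS} columns, got {len(fields)}"
                )
            accession = fields[_COL_QUERY_ACC]
            if accession == "-":
                accession = fields[_COL_QUERY_NAME]
            try:
                i_evalue = float(fields[_COL_I_EVALUE])
                bit_score = float(fields[_COL_DOM_SCORE])
                env_from = int(fields[_COL_ENV_FROM])
                env_to = int(fields[_COL_ENV_TO])
            except ValueError as exc:
                raise HmmerParseError(f"{path}: line {lineno}: {exc}") from None
            if max_i_evalue is not None and i_evalue > max_i_evalue:
                continue
            hits.append(
                DomainHit(
                    protein_id=fields[_COL_TARGET_NAME],
                    domain_accession=strip_accession_version(accession),
                    ali_start=env_from,
                    ali_end=env_to,
                    bit_score=bit_score,
                    i_evalue=i_evalue,
                )
            )
    return hits


def hits_by_protein(hits: Iterable[DomainHit]) -> "OrderedDict[str, list[DomainHit]]":
    """Group hits by protein id, preserving input order within each bucket."""
    buckets: OrderedDict[str, list[DomainHit]] = OrderedDict()
    for hit in hits:
        buckets.setdefault(hit.protein_id, []).append(hit)
    return buckets
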