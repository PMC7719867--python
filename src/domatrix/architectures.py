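"""Domain architectures: the ordered domain content of a protein.

A protein's architecture is its domain accessions joined by ``_`` in
ascending start-coordinate order.  Order matters — the same domain set in a
different order can mean a different gene function — and tandem repeats are
kept, so a large clostridial toxin may legitimately carry the same repeat
domain five times in a row.  The underscore delimiter is load-bearing:
accessions containing ``_`` are rejected at parse time so the string always
splits back into its units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ArchitectureError
from .hmmer_io import DomainHit, hits_by_protein

__all__ = ["ProteinArchitecture", "build_architecture", "architectures_for_genome"]

DELIMITER = "_"


@dataclass(frozen=True)
class ProteinArchitecture:
    protein_id: str
    architecture: str
    n_units: int

    def __post_init__(self) -> None:
        units = self.architecture.split(DELIMITER)
        if not self.architecture or len(units) != self.n_units:
            raise ArchitectureError(
                f"architecture {self.architecture!r} does not split into {self.n_units} units"
            )


def build_architecture(hits: Iterable[DomainHit]) -> ProteinArchitecture:
    """Collapse one protein's hits into its architecture string.

    Hits are sorted by (start, end, accession) ascending — input order is
    irrelevant — and joined with ``_``.  Overlapping hits are kept as
    reported; no overlap resolution is attempted.

    Raises
    ------
    ArchitectureError
        If the hit list is empty or spans more than one protein id.
    """
    hits = list(hits)
    if not hits:
        raise ArchitectureError("cannot build an architecture from zero hits")
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ArchitectureError(
            f"hits span multiple proteins: {sorted(protein_ids)}"
        )
    ordered = sorted(hits, key=lambda h: (h.ali_start, h.ali_end, h.domain_accession))
    return ProteinArchitecture(
        protein_id=hits[0].protein_id,
        architecture=DELIMITER.join(h.domain_accession for h in ordered),
        n_units=len(ordered),
    )


def architectures_for_genome(hits: Iterable[DomainHit]) -> list[ProteinArchitecture]:
    """One architecture per protein with at least one hit, in first-hit order.

    Duplicate architecture strings from distinct proteins are all retained;
    counting happens downstream in the matrix build.
    """
    return [build_architecture(bucket) for bucket in hits_by_protein(hits).values()]
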