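"""Exception hierarchy.

All domatrix errors derive from :class:`DomatrixError`, so callers (and the
CLI) can distinguish data/format problems from programming errors.
"""


class DomatrixError(Exception):
    """Base class for all domatrix errors."""


class ManifestError(DomatrixError):
    """Malformed genome manifest (duplicate ids, short lines)."""


class HmmerParseError(DomatrixError):
    """Malformed hmmsearch per-domain tabular (domtblout) line."""


class ArchitectureError(DomatrixError):
    """Invalid input to domain-architecture construction."""


class MatrixFormatError(DomatrixError):
    """Corrupt, incomplete, or unknown-version matrix folder."""


class LabelError(DomatrixError, KeyError):
    """A requested genome or feature label is not in the matrix."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class ProteinStoreError(DomatrixError):
    """Protein-id store missing (matrix was built without the keep option)."""
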