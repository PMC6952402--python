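"""Exception hierarchy.

Three families so the CLI can map failures to distinct exit codes:
configuration problems (exit 2), malformed or inconsistent data (exit 3),
and internal invariant violations (exit 4).
"""


class PhylocurateError(Exception):
    """Base class for all package errors."""


class ConfigError(PhylocurateError):
    """Invalid or incomplete pipeline configuration."""


class DataError(PhylocurateError):
    """Malformed input data."""


class AlignmentShapeError(DataError):
    """Rows of an alignment have unequal lengths, or length mismatch between
    sequences that must be comparable."""


class HeaderError(DataError):
    """A FASTA header or tree leaf label does not follow the configured
    taxon/sequence-id scheme."""


class EmptyInputError(DataError):
    """An operation that requires data received none."""


class NewickParseError(DataError):
    """Malformed newick input."""


class ConsistencyError(PhylocurateError):
    """Internal cross-object inconsistency (e.g. prune result referencing
    labels absent from the alignment, overlapping partitions)."""
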