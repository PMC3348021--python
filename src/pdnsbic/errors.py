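"""Exception taxonomy.

``DataError`` subclasses map to CLI exit code 2 (bad data); ``UsageError``
situations (bad flags) are handled by the argument parser and exit 1.
"""


class DataError(ValueError):
    """Base class for all input/data-contract violations."""


class MatrixFormatError(DataError):
    """Malformed expression-matrix file (duplicates, non-numeric cells, ...)."""


class DimensionError(DataError):
    """Matrix too small for pair-column combinatorics (need n >= 2, m >= 3)."""


class IdentifierResolutionError(DataError):
    """A gene/condition identifier in a bicluster file is absent from the matrix."""


class DegenerateBiclusterError(DataError):
    """Bicluster or configuration too small for the requested operation."""
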