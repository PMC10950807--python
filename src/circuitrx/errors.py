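"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`CircuitrxError`
so the CLI can map any pipeline failure to a single-line diagnostic and a
non-zero exit status.
"""


class CircuitrxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CircuitrxError):
    """Invalid or incomplete disease definition."""


class FormatError(CircuitrxError):
    """Malformed tabular input (bad columns, duplicates, non-numeric cells)."""


class AlignmentError(CircuitrxError):
    """Row/sample spaces of two matrices cannot be aligned."""


class MapLookupError(CircuitrxError):
    """A requested circuit, gene or disease identifier is unknown."""


class EmptyMapError(CircuitrxError):
    """Disease-map construction produced no circuits."""


class ImputationError(CircuitrxError):
    """Missing-value imputation cannot proceed (e.g. fully missing column)."""


class FeatureGuardError(CircuitrxError):
    """Exhaustive Shapley enumeration refused: too many features."""
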