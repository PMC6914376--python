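"""Exception hierarchy.

Exit codes used by the CLI: 2 configuration, 3 data integrity,
4 precondition/malformed input.
"""


class NbspanelError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(NbspanelError):
    """Invalid or missing configuration (bad paths, inconsistent thresholds)."""

    exit_code = 2


class DataIntegrityError(NbspanelError):
    """Inputs are internally inconsistent (e.g. missing depth at a call site)."""

    exit_code = 3


class PreconditionError(NbspanelError):
    """An operation's documented precondition was violated."""

    exit_code = 4


class MalformedInputError(PreconditionError):
    """Structurally invalid record (e.g. genotype index out of range)."""


class ReferenceMismatchError(PreconditionError):
    """Variant REF allele does not match the reference sequence at its position."""


class LeftExtensionError(NbspanelError):
    """Normalization would need to extend left past position 1 of the contig."""

    exit_code = 4


class BoundsError(NbspanelError):
    """Position outside the addressable range of a sequence or region."""

    exit_code = 4
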