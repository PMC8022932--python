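"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: usage errors exit 2 (click),
:class:`FormatError` and subclasses exit 3, anything else exits 4.
"""


class ScreenvarError(Exception):
    """Base class for all package errors."""


class FormatError(ScreenvarError):
    """Malformed or invalid input file (FASTA/GFF3/VCF/TSV)."""


class UnsupportedVariantError(ScreenvarError):
    """Allele pair outside the supported SNV/insertion/deletion classes."""


class ContractError(ScreenvarError):
    """A documented precondition between pipeline stages was violated."""


class ConfigError(ScreenvarError):
    """Invalid simulation or pipeline configuration."""
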