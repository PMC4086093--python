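"""Exception hierarchy."""


class AfdistError(Exception):
    """Base class for all package errors."""


class InputFormatError(AfdistError, ValueError):
    """Malformed input data (FASTA, pattern file, Phylip matrix)."""


class ContractError(AfdistError, ValueError):
    """An operation was called with arguments violating its contract."""
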