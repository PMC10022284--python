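"""Exception hierarchy."""


class AkidetectError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AkidetectError):
    """A configuration file or dialect mapping is invalid or incomplete."""


class DataFormatError(AkidetectError):
    """An input file cannot be parsed; message names the file (and line where known)."""


class PreconditionError(AkidetectError):
    """An operation was called on data that violates its stated precondition."""
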