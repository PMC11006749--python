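"""Exception types shared across the pipeline."""


class AbtslcError(Exception):
    """Base class for all package errors."""


class MafFormatError(AbtslcError):
    """A MAF file violates the expected tab-separated dialect."""


class ConfigurationError(AbtslcError):
    """A user-supplied option or config file is invalid."""


class DegenerateInputError(AbtslcError):
    """Input is structurally valid but statistically degenerate
    (e.g. all x identical in a regression design)."""
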