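"""Exception hierarchy shared across the pipeline."""


class PginError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PginError):
    """A file does not conform to its declared dialect."""


class ConfigError(PginError):
    """Run configuration is malformed or names an unknown preset."""


class ParameterError(PginError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(PginError):
    """Input is structurally valid but carries no usable information
    (all-zero catalog, constant vector, empty group)."""


class UndefinedScoreError(PginError):
    """A score's denominator is empty; the sample fails coverage QC."""


class FitError(PginError):
    """A model fit failed to converge or the likelihood is degenerate."""


class ChannelOrderError(PginError):
    """Two mutation catalogs disagree on the 96-channel ordering."""
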