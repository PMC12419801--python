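"""Exception hierarchy shared across the pipeline."""


class SuperfamError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SuperfamError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(SuperfamError):
    """Parsed content violates a domain invariant (coordinates, labels, ...)."""


class ParameterError(SuperfamError):
    """A configuration or simulation parameter is out of its feasible range."""
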