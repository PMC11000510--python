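"""Exception taxonomy shared across the toolbox."""


class MultidfcError(Exception):
    """Base class for all toolbox errors."""


class FormatError(MultidfcError):
    """A file does not have the expected shape or column layout."""


class ParseError(MultidfcError):
    """A cell of a delimited file could not be parsed."""


class ValidationError(MultidfcError):
    """A container violates one of its invariants."""


class ParameterError(MultidfcError):
    """A hyperparameter is outside its admissible range."""


class AssemblyError(MultidfcError):
    """A dFC array could not be assembled from per-method results."""


class ContainerError(MultidfcError):
    """An on-disk container is missing datasets or is unreadable."""


class FitError(MultidfcError):
    """A model fit failed after all retries."""
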