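"""Exception types shared across the package."""


class RrbskitError(Exception):
    """Base class for package errors."""


class ParameterError(RrbskitError, ValueError):
    """An argument is outside its documented domain."""


class SizingError(RrbskitError, ValueError):
    """A simulated genome is too small to host the requested features."""


class UndefinedResultError(RrbskitError, ValueError):
    """The requested statistic is undefined for the given input
    (e.g. zero rank variance, too few informative read-bases)."""
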