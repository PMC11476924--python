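"""Exception hierarchy shared across the package."""


class ChemoatlasError(Exception):
    """Base class for all package-specific errors."""


class UnknownGeneError(ChemoatlasError, KeyError):
    """A gene symbol (or alias) is not present in the registry."""


class StageAnnotationError(ChemoatlasError, ValueError):
    """A sample label could not be mapped onto the harmonized stage vocabulary."""


class ParseError(ChemoatlasError, ValueError):
    """An input file is malformed."""


class InsufficientSamplesError(ChemoatlasError, ValueError):
    """A contrast arm (or the set of complete pairs) is too small to test."""
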