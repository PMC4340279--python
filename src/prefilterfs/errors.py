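"""Exception hierarchy shared across the package."""


class PrefilterError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PrefilterError):
    """A file does not conform to its documented on-disk dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class IdentifierCollisionError(PrefilterError):
    """Duplicate feature or sample identifiers where uniqueness is required."""


class AmbiguousMappingError(PrefilterError):
    """A probe maps to more than one feature; collapsing would have to guess."""


class InsufficientDataError(PrefilterError):
    """A statistical test was asked to run on too few observations."""


class DegenerateLabelsError(PrefilterError):
    """An operation requiring two classes received labels with fewer."""


class EmptyDatasetError(PrefilterError):
    """A downstream stage refused an empty filtered dataset."""


class UndefinedMetricError(PrefilterError):
    """A metric is undefined for the given inputs (e.g. AUC with one class)."""
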