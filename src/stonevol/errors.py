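"""Exception hierarchy for the stonevol pipeline."""


class StonevolError(Exception):
    """Base class for all stonevol errors."""


class NoInputError(StonevolError):
    """No usable input files were found."""


class AmbiguousSeriesError(StonevolError):
    """A directory mixes images from more than one CT series."""


class GeometryError(StonevolError):
    """Image geometry is inconsistent (shapes, spacing, positions)."""


class UnknownLabelError(StonevolError, KeyError):
    """A requested stone label is absent from the label map."""


class DomainError(StonevolError, ValueError):
    """An input value is outside the operation's domain."""


class UndefinedStatisticError(StonevolError, ValueError):
    """A statistic is undefined for the given data (e.g. constant vector)."""
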