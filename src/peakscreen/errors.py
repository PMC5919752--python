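"""Exception hierarchy shared across the package."""


class PeakScreenError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(PeakScreenError, ValueError):
    """Invalid genomic coordinates (inverted span, out-of-range base)."""


class FormatError(PeakScreenError, ValueError):
    """Malformed input file or record (overlapping bedGraph records, bad columns)."""


class SequenceError(PeakScreenError, ValueError):
    """Invalid nucleotide or IUPAC character."""


class NormalizationError(PeakScreenError, ValueError):
    """Library-size normalization cannot be performed (zero total)."""


class ShapeError(PeakScreenError, ValueError):
    """Mismatched chromosome sets/lengths or vector lengths."""


class BoundsError(PeakScreenError, ValueError):
    """A region falls outside the coverage track it is evaluated on."""


class ConfigurationError(PeakScreenError, ValueError):
    """Invalid parameter value or unsatisfiable simulation configuration."""


class UndefinedStatisticError(PeakScreenError, ValueError):
    """A statistic is undefined for the given input (constant vector, zero ratio)."""
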