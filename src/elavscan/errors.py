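"""Exception hierarchy shared across the pipeline stages."""


class ElavScanError(Exception):
    """Base class for all pipeline errors."""


class FormatError(ElavScanError):
    """A file does not conform to the expected on-disk format."""


class AlignmentFormatError(FormatError):
    """Aligned-FASTA rows are inconsistent (e.g. unequal widths)."""


class SpeciesLookupError(ElavScanError, KeyError):
    """A requested species id is absent from an alignment."""


class CoordinateError(ElavScanError, ValueError):
    """An interval does not fit on the sequence it refers to."""


class ConfigError(ElavScanError, ValueError):
    """An invalid parameter value was supplied."""


class AmbiguityError(ElavScanError):
    """An operation that requires a unique target found zero or several."""


class DegenerateDataError(ElavScanError):
    """Input is degenerate for the requested statistic (e.g. all-zero differences)."""


class NormalizationError(ElavScanError, ValueError):
    """Reference expression values are unusable (zero or negative)."""


class PlacementError(ElavScanError):
    """Synthetic objects could not be placed without overlap."""


class CongruenceError(ElavScanError, ValueError):
    """Two arrays that must share a shape do not."""
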