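"""Exception hierarchy shared across the pipeline stages."""


class TwinsigError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TwinsigError):
    """A configuration object violates one of its invariants."""


class SchedulingError(TwinsigError):
    """A stimulus event does not fit the recording with its analysis windows."""


class StructuralError(TwinsigError):
    """Traces within a recording are inconsistent (e.g. unequal lengths)."""


class TraceInputError(TwinsigError):
    """A fluorescence series contains non-finite values."""


class DegenerateBaselineError(TwinsigError):
    """Pre-stimulus baseline f0 <= 0: background subtraction was inadequate."""


class CalibrationError(TwinsigError):
    """A calibration divisor (ionomycin or KCl response) is nonpositive."""


class IncompleteProtocolError(TwinsigError):
    """A required stimulus (ionomycin or KCl) is missing from a cell's record."""


class PairingError(TwinsigError):
    """Subject summaries do not form a valid twin pair for contrasting."""


class InsufficientCellsError(TwinsigError):
    """Fewer than two cells remain for a subject after outlier removal."""


class ContainmentError(TwinsigError):
    """A gene set is not contained in the declared universe."""


class ParseError(TwinsigError):
    """An input file violates the expected schema."""
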