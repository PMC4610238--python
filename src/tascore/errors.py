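"""Exception hierarchy for tascore."""


class TascoreError(Exception):
    """Base class for all tascore errors."""


class InvalidConfigError(TascoreError, ValueError):
    """A configuration object violates its invariants."""


class FitError(TascoreError, ValueError):
    """A dose-response series cannot be fitted."""


class ParseError(TascoreError, ValueError):
    """A file could not be parsed; message carries the line number."""


class EmptyNetworkError(TascoreError, ValueError):
    """All edges were filtered out during network assembly."""


class IncompatibilityError(TascoreError, ValueError):
    """Two objects (matrix/network, matrix/matrix) share no common ids."""


class UndefinedDistanceError(TascoreError, ValueError):
    """A pairwise distance is undefined (zero norm, too few shared coords)."""


class UndefinedCorrelationError(TascoreError, ValueError):
    """A correlation is undefined (constant vector)."""


class LookupError_(TascoreError, KeyError):
    """Unknown sample or target id."""
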