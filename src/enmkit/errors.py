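"""Exception hierarchy used across the toolkit.

Everything derives from :class:`EnmkitError` so callers can catch the
package's failures with a single ``except`` clause.
"""


class EnmkitError(Exception):
    """Base class for all enmkit errors."""


class ConfigError(EnmkitError, ValueError):
    """Invalid configuration (bad grid, non-PSD correlation, unknown variable...)."""


class AlignmentError(EnmkitError, ValueError):
    """Rasters or tables that must share a grid / key set do not."""


class OutOfBoundsError(EnmkitError, ValueError):
    """Points or tiles fall outside the grid extent."""


class DomainError(EnmkitError, ValueError):
    """Values outside their admissible range (probabilities, binary labels...)."""


class InsufficientDataError(EnmkitError, ValueError):
    """Too few occurrences / positives / rows for the requested operation."""


class ConvergenceError(EnmkitError, RuntimeError):
    """Optimizer failed to converge within the iteration cap."""


class TuningError(EnmkitError, RuntimeError):
    """Every candidate in a tuning grid was disqualified."""


class DegenerateReferenceError(EnmkitError, ValueError):
    """A reference envelope variable has no spread (max == min)."""


class SelectionError(EnmkitError, RuntimeError):
    """Variable screening eliminated every candidate."""


class StateError(EnmkitError, RuntimeError):
    """Operation requested on an object in the wrong state (e.g. unfitted model)."""
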