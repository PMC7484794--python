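"""Exceptions raised across the corona-analysis pipeline.

Every stage raises a subclass of :class:`CoronaError` so callers (and the
CLI) can distinguish bad measurements from bad configuration.
"""


class CoronaError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(CoronaError, ValueError):
    """A physical measurement violates its preconditions (e.g. negative
    absorbance, zero nanoparticle concentration, corrected A280 <= 0)."""


class EmptySampleError(CoronaError, ValueError):
    """A sample carries no signal (all emPAI zero, all copies zero)."""


class ConfigurationError(CoronaError, ValueError):
    """Inconsistent run configuration (missing sample measurement, no
    captured column, unknown label...)."""


class InsufficientDataError(CoronaError, ValueError):
    """Not enough observations for the requested operation."""


class InvalidInputError(CoronaError, ValueError):
    """Non-finite or otherwise malformed numeric input."""


class InvalidSequenceError(CoronaError, ValueError):
    """A protein sequence is empty, too short, or contains characters
    outside the 20 standard amino acids."""


class DegenerateGeometryError(CoronaError, ValueError):
    """Atom coordinates are too few or coplanar/colinear for a 3-D
    cross-section computation."""


class IncompleteInputError(CoronaError, ValueError):
    """A required per-protein input (e.g. a footprint) is missing."""


class InsufficientBaselineError(CoronaError, ValueError):
    """A drift-correction baseline window contains fewer than two points."""


class EmptyDistributionError(CoronaError, ValueError):
    """An affinity distribution has zero total weight."""


class ParseError(CoronaError, ValueError):
    """A tabular input file is malformed; carries the offending line."""
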