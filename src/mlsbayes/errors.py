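"""Typed exceptions shared across the package.

Zero-mass conditioning, annihilated populations and malformed inputs all
raise distinct types so callers can react precisely; nothing in the
package returns NaN to signal an undefined quantity.
"""


class MLSBayesError(Exception):
    """Base class for all package errors."""


class ShapeMismatchError(MLSBayesError):
    """Array shape does not match the hierarchy structure."""


class NegativeEntryError(MLSBayesError):
    """An abundance or fitness entry is negative."""


class AllZeroError(MLSBayesError):
    """Every entry of a raw abundance array is zero; nothing to normalize."""


class NormalizationError(MLSBayesError):
    """Distribution entries do not sum to one within tolerance."""


class UnknownLevelError(MLSBayesError):
    """Level name not present in the hierarchy structure."""


class UnknownTypeError(MLSBayesError):
    """Type label not present at the given level."""


class EmptyCollectiveError(MLSBayesError):
    """Conditioning on a type with zero marginal mass; conditional undefined."""


class ExtinctionError(MLSBayesError):
    """Total weighted mass (model evidence) is zero: population annihilated.

    ``step`` carries the failing time index when raised inside a trajectory.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class InvalidMoveError(MLSBayesError):
    """Structure move payload inconsistent with the current state."""


class InvalidStochasticMatrixError(MLSBayesError):
    """Probability vector or transition-matrix row does not sum to one."""


class MissingSpecError(MLSBayesError):
    """Synergy specification does not cover a required type or state."""


class ConfigError(MLSBayesError):
    """Run configuration file is missing, malformed or fails validation."""
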