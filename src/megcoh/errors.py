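"""Exception hierarchy shared across the package."""


class MegcohError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MegcohError, ValueError):
    """A parameter violates its documented precondition."""


class GeometryError(MegcohError):
    """Inconsistent conductor / sensor / source geometry."""


class SingularGeometryError(GeometryError):
    """Forward-model geometry is singular (e.g. dipole at the sphere center)."""


class MeshFormatError(MegcohError):
    """A mesh file could not be parsed; the message names the offending line."""


class UnsupportedMeshError(MeshFormatError):
    """The mesh file parses but uses features we do not support (non-triangles)."""


class InsufficientMeshError(MegcohError):
    """The mesh is too small to host the requested patch."""


class ShapeError(MegcohError, ValueError):
    """Array dimensions are inconsistent."""


class ConvergenceError(MegcohError):
    """An iterative loop exhausted its iteration budget.

    Carries ``best_achieved``, the closest value reached before giving up.
    """

    def __init__(self, message, best_achieved=None):
        super().__init__(message)
        self.best_achieved = best_achieved


class UndefinedSNRError(MegcohError):
    """SNR is undefined because the clean signal is identically zero."""


class RankDeficiencyError(MegcohError):
    """Unregularized system is rank deficient; regularization is required."""


class CornerUndefinedError(MegcohError):
    """L-curve corner cannot be determined (degenerate or too-short curve)."""


class InsufficientDataError(MegcohError):
    """Time series shorter than one Welch segment."""


class UndefinedCoherenceError(MegcohError):
    """Coherence undefined because an autospectrum vanishes in the band."""


class UndefinedROCError(MegcohError):
    """ROC undefined (e.g. no ground-truth vertices left after exclusion)."""


class DegenerateTestError(MegcohError):
    """Statistical test degenerate (zero-variance differences)."""


class IncompleteDesignError(MegcohError):
    """Factorial study table is missing cells; the message lists the gaps."""


class ConfigurationError(MegcohError):
    """Invalid simulation configuration (e.g. overlapping patches)."""


class StudyError(MegcohError):
    """Too many cells of a Monte-Carlo study failed."""
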