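"""Exception and warning types used across morphfit."""


class MorphfitError(Exception):
    """Base class for all morphfit errors."""


class InvalidInputError(MorphfitError, ValueError):
    """Malformed or non-finite input data."""


class CorpusError(MorphfitError, ValueError):
    """A training corpus violates the shared-topology requirement."""


class RankError(MorphfitError, ValueError):
    """More principal modes requested than the data can support."""


class InsufficientCorrespondencesError(MorphfitError, ValueError):
    """Too few 2D-3D correspondences for pose estimation."""


class DegenerateGeometryError(MorphfitError, ValueError):
    """3D correspondences are collinear (pose is unobservable)."""


class SingularSystemError(MorphfitError, ValueError):
    """The unregularized shape-coefficient system is rank deficient."""


class UndefinedLossError(MorphfitError, ValueError):
    """A loss is undefined for the given input (e.g. empty mask)."""


class MissingTermError(MorphfitError, KeyError):
    """A required loss component was not supplied."""


class ZeroVarianceWarning(UserWarning):
    """The corpus has (numerically) zero variance along requested modes."""


class CoplanarWarning(UserWarning):
    """3D correspondences are coplanar; pose is recoverable but fragile."""


class ConvergenceWarning(UserWarning):
    """An iterative solver stopped before reaching its tolerance."""
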