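"""Exception hierarchy.

All domain errors derive from :class:`CochleoplanError` so callers (and the
CLI) can distinguish bad input / degenerate geometry from programming errors.
"""


class CochleoplanError(ValueError):
    """Base class for all cochleoplan domain errors."""


class LandmarkError(CochleoplanError):
    """Invalid or degenerate anatomical landmark configuration."""


class FrameError(CochleoplanError):
    """Cochlear coordinate frame cannot be constructed or is invalid."""


class MeshError(CochleoplanError):
    """Surface mesh is invalid (bad indices, non-finite vertices, empty)."""


class MeshReadError(MeshError):
    """A mesh file could not be parsed."""


class TruncationError(CochleoplanError):
    """No basal scala tympani surface found after truncation."""


class SectionError(CochleoplanError):
    """A radial cross section collapsed or too few sections survive."""


class SplineError(CochleoplanError):
    """Centerline spline cannot be fitted or was evaluated out of domain."""


class IntersectionError(CochleoplanError):
    """A trajectory does not exit through the mesh surface."""


class PlanError(CochleoplanError):
    """Planning produced no usable trajectories or a plan file is invalid."""


class RegistrationError(CochleoplanError):
    """Fiducial registration is under-determined (too few / collinear pairs)."""


class EvaluationError(CochleoplanError):
    """An evaluation metric is undefined for the given input."""


class PhantomError(CochleoplanError):
    """Phantom specification violates its own invariants."""
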