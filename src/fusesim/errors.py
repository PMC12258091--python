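"""Exception hierarchy for fusesim."""


class FusesimError(Exception):
    """Base class for all fusesim errors."""


class ParameterError(FusesimError, ValueError):
    """A configuration or geometry parameter violates its constraints."""


class GeometryError(FusesimError):
    """The mesh or a derived geometric entity is invalid or empty."""


class AssemblyError(FusesimError):
    """Finite-element assembly failed (e.g. inverted element)."""


class SolverError(FusesimError):
    """The linear solve failed (singular or ill-conditioned system)."""


class CalibrationError(FusesimError):
    """An iterative calibration (diffusion coefficient, flexion moment) failed."""
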