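"""Exception hierarchy shared across the package.

Every error raised by hairpinxb derives from :class:`HairpinXbError`, so
callers can catch one base class at pipeline boundaries while the
subclasses keep the failure modes distinguishable (bad file, bad geometry,
bad fit, bad configuration).
"""


class HairpinXbError(Exception):
    """Base class for all package errors."""


class FormatError(HairpinXbError):
    """A structure or table file could not be parsed."""


class TopologyError(HairpinXbError):
    """Conformers in a pool disagree in atom count, names, or order."""


class SelectionError(HairpinXbError):
    """An atom selector (res_index, atom_name) did not resolve."""


class DegenerateGeometryError(HairpinXbError):
    """Coincident or collinear atoms make a geometric quantity undefined."""


class ConstructionError(HairpinXbError):
    """The synthetic template builder could not realize the requested geometry."""


class EnrichmentError(HairpinXbError):
    """Halogen-bond-constrained conformers could not be generated."""


class ConfigError(HairpinXbError):
    """Invalid run or generator configuration."""


class InsufficientDataError(HairpinXbError):
    """Too few observations for the requested fit."""


class CalibrationError(HairpinXbError):
    """Non-positive buildup rate passed to the distance calibration."""


class SingularFitError(HairpinXbError):
    """Design matrix is singular / all-zero; no meaningful fit exists."""


class ConvergenceError(HairpinXbError):
    """Iterative fit failed to converge; carries the Q trace."""

    def __init__(self, message, q_trace=None):
        super().__init__(message)
        self.q_trace = list(q_trace) if q_trace is not None else []


class LabelingError(HairpinXbError):
    """Per-conformer label vector does not match the pool size."""


class UnknownElementError(HairpinXbError):
    """Element missing from the van der Waals radius table."""


class DomainError(HairpinXbError):
    """Argument outside the mathematical domain (e.g. population 0 or 1)."""
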