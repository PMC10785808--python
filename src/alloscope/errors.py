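"""Exception hierarchy shared by all analysis stages."""


class AlloscopeError(Exception):
    """Base class for every error raised by this package."""


class FormatError(AlloscopeError):
    """A file could not be parsed under the named format."""


class ConsistencyError(AlloscopeError):
    """Frames of one ensemble disagree on atom count or identity."""


class SelectionError(AlloscopeError):
    """An atom selection matched nothing, or a required atom is absent."""


class DegenerateFitError(AlloscopeError):
    """Superposition fit set is too small or collinear."""


class InsufficientDataError(AlloscopeError):
    """Too few frames for the requested statistic."""


class GeometryError(AlloscopeError):
    """Requested chain geometry is infeasible."""


class CovarianceSpecError(AlloscopeError):
    """Block-covariance specification is invalid or not PSD."""


class PerturbationSpecError(AlloscopeError):
    """Perturbation-field specification is invalid."""


class PairingError(AlloscopeError):
    """Equilibrium/perturbed windows cannot be matched frame-by-frame."""


class CorrelationRangeError(AlloscopeError):
    """A correlation magnitude exceeds 1 beyond numerical tolerance."""


class DegenerateRangeError(AlloscopeError):
    """Min-max normalization of a constant score vector was requested."""


class CoverageError(AlloscopeError):
    """A method's score vector does not cover the requested residues."""


class FormattingError(AlloscopeError):
    """A value cannot be represented in a fixed-width output field."""
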