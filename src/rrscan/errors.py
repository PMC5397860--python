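"""Exception hierarchy.

Every error the package raises deliberately derives from :class:`RRScanError`
so callers can catch the package's failures without masking programming
errors.
"""


class RRScanError(Exception):
    """Base class for all rrscan errors."""


class FormatError(RRScanError):
    """A file does not parse in its declared format."""


class MassAssignmentError(RRScanError):
    """An atom's mass cannot be inferred from its element or name."""


class TopologyError(RRScanError):
    """Atom/residue bookkeeping is inconsistent (e.g. atom-count mismatch)."""


class SelectionError(RRScanError):
    """An atom selection resolves to nothing."""


class RangeError(RRScanError):
    """A residue range is not present in the topology."""


class SpecError(RRScanError):
    """A synthetic-data specification is invalid."""


class StabilityError(RRScanError):
    """The integrator diverged; a smaller timestep is needed."""


class DegenerateFitError(RRScanError):
    """Superposition is ill-defined (<3 atoms or collinear geometry)."""


class ParameterError(RRScanError):
    """An analysis parameter is out of range."""


class ProvenanceError(RRScanError):
    """A landscape/cluster operation references an unknown ensemble id."""


class InsufficientDataError(RRScanError):
    """Too few frames for the requested statistic."""


class ConditioningError(RRScanError):
    """A covariance matrix is numerically singular beyond regularization."""


class EmptySpectrumError(RRScanError):
    """No quasi-harmonic mode survives the exclusion policy."""


class MissingReferenceError(RRScanError):
    """A relative-entropy table lacks its reference simulation."""


class InputError(RRScanError):
    """Mismatched or missing inputs to a comparison."""


class ConfigError(RRScanError):
    """A scan configuration is invalid."""
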