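"""Exception hierarchy for the facepulse pipeline.

All pipeline errors derive from :class:`FacepulseError` so callers can catch
one base class at the CLI boundary.
"""


class FacepulseError(Exception):
    """Base class for all facepulse errors."""


class DecodeError(FacepulseError):
    """A video/frame-stack file could not be decoded."""


class ConfigurationError(FacepulseError):
    """Invalid or missing configuration (fps metadata, band limits, schema)."""


class BoundsError(FacepulseError):
    """A region of interest lies (partly) outside the frame."""


class EmptyInputError(FacepulseError):
    """An operation received an empty frame sequence or signal."""


class InsufficientDataError(FacepulseError):
    """Signal/series too short for the requested analysis."""


class RangeError(FacepulseError):
    """A requested analysis window lies outside the retained signal span."""


class NoSignalError(FacepulseError):
    """No in-band spectral energy: the dominant frequency is undefined."""


class MissingRegionError(FacepulseError):
    """A face region required to assemble the feature vector is absent."""


class DegenerateRangeError(FacepulseError):
    """A variable is constant; the [-1, 1] normalization map is undefined."""


class InsufficientSamplesError(FacepulseError):
    """Too few samples for the 70/15/15 data division."""


class AlignmentError(FacepulseError):
    """Input and target series have mismatched lengths or cadence."""


class InsufficientHistoryError(FacepulseError):
    """Target history shorter than the network's delay line."""


class DegenerateFitError(FacepulseError):
    """Zero-variance predictor: the linear fit is undefined."""


class ScenarioError(FacepulseError):
    """A synthetic pulse scenario violates its physiological constraints."""
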