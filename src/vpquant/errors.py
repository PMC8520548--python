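"""Exception hierarchy for VP SPECT quantification.

Every error raised by the package derives from :class:`VPQuantError`, so
callers (and the CLI) can catch one type. The subclasses mirror the
failure modes of a clinical workflow: unreadable or off-protocol DICOM
data, physically implausible count arithmetic, and infeasible planning
requests.
"""


class VPQuantError(Exception):
    """Base class for all vpquant errors."""


class FormatError(VPQuantError):
    """The file is not the DICOM object kind expected (e.g. not NM modality)."""


class UnreadableStudyError(VPQuantError):
    """Required DICOM metadata (energy windows, timing) is missing or corrupt."""


class ProtocolError(VPQuantError):
    """The study structurally cannot be a dual-window projection study."""


class UndefinedRatioError(VPQuantError):
    """A count ratio has a zero denominator (e.g. no scatter-window counts)."""


class IntervalError(VPQuantError):
    """A decay interval is negative; the caller must orient intervals."""


class ImplausibleStudyError(VPQuantError):
    """Count arithmetic produced a physically impossible value
    (e.g. perfusion counts not above residual ventilation)."""


class InconsistencyError(VPQuantError):
    """Records contradict each other (e.g. injection-site activity exceeding
    the decayed dispensed activity, or dispense time after scan time)."""


class MissingRecordError(VPQuantError):
    """A required radiopharmacy or imaging record is absent."""


class DegenerateDesignError(VPQuantError):
    """Regression design matrix is singular (constant predictor)."""


class InsufficientDataError(VPQuantError):
    """Too few observations to fit the model."""


class OutOfDomainError(VPQuantError):
    """A prediction fell outside the physically meaningful domain
    (non-positive predicted count rate)."""


class InfeasibleError(VPQuantError):
    """No dose/delay combination can achieve the requested target."""
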