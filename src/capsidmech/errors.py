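"""Exception hierarchy for capsidmech."""


class CapsidMechError(Exception):
    """Base class for all capsidmech errors."""


class ContactNotFoundError(CapsidMechError):
    """No contact point improves sufficiently over a single-line fit."""


class GlassLikeCurveError(CapsidMechError):
    """Tip–sample indentation is negligible: the curve behaves like a hard
    (effectively infinitely stiff) substrate and no particle spring constant
    can be extracted."""


class DegenerateTraceError(CapsidMechError):
    """Thermal deflection trace has zero variance or is otherwise unusable."""


class CalibrationError(CapsidMechError):
    """Calibration is missing, invalid, or could not be computed."""


class ProtocolError(CapsidMechError):
    """Simulation protocol is degenerate (e.g. empty contact region)."""


class InsufficientDataError(CapsidMechError):
    """Too few samples or particles for the requested operation."""
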