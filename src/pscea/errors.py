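"""Exception hierarchy for the CEA pipeline."""


class PsceaError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(PsceaError, ValueError):
    """A numeric argument violates its precondition (e.g. non-positive median)."""


class CurveFormatError(PsceaError, ValueError):
    """A survivor-curve file or array violates the curve invariants."""


class InvalidScenarioError(PsceaError, ValueError):
    """A sensitivity scenario produced curves that violate model invariants."""


class ConfigurationError(PsceaError, ValueError):
    """A configuration key, mode or sensitivity target is unknown or inconsistent."""
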