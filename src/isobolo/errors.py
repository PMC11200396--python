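"""Exception hierarchy for plate-endpoint and potency computations."""


class IsoboloError(Exception):
    """Base class for all package-specific errors."""


class InvalidControlError(IsoboloError):
    """Control signal is zero, negative or missing, so normalisation is undefined."""


class DegenerateWindowError(IsoboloError):
    """Maximum-release OD does not exceed blank OD; the LDH window has no width."""


class RankDeficiencyError(IsoboloError):
    """Standard-curve concentrations are all identical; no line can be fitted."""


class NonInvertibleCurveError(IsoboloError):
    """Standard curve has zero slope and cannot be inverted."""


class InsufficientDesignError(IsoboloError):
    """Too few distinct positive concentrations to identify a sigmoid."""


class FitFailureError(IsoboloError):
    """Concentration-response fit did not converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateVarianceError(IsoboloError):
    """Both potency SEMs are zero; the t statistic is undefined."""
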