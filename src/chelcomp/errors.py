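"""Exception hierarchy shared across the package."""


class ChelcompError(Exception):
    """Base class for all package errors."""


class ValidationError(ChelcompError, ValueError):
    """Invalid user input (concentrations, configs, tables)."""


class SelectionError(ChelcompError):
    """No peak survived the selection criteria.

    Carries a ``reasons`` mapping of peak_id -> failing criterion.
    """

    def __init__(self, message: str, reasons: dict | None = None):
        super().__init__(message)
        self.reasons = dict(reasons or {})


class FitError(ChelcompError):
    """Dissociation-constant fit could not be performed."""


class NonInformativePointWarning(UserWarning):
    """A titration point carries no binding information and was dropped."""
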