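"""Exception hierarchy shared across fibromech modules."""


class FibromechError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FibromechError, ValueError):
    """A physical parameter is outside its valid domain."""


class ValidationError(FibromechError, ValueError):
    """An input container violates its invariants."""


class InsufficientDataError(FibromechError):
    """Too few samples to run the requested estimator."""


class NoContactError(FibromechError):
    """No contact point could be located on an approach curve."""


class FitError(FibromechError):
    """A model fit failed or its assumptions were violated."""


class NoPeriodError(FibromechError):
    """No significant axial period found in a profile."""


class NoFitError(FitError):
    """A dose-response fit could not be performed (e.g. flat response)."""


class CycleCountError(FibromechError):
    """A compression trace contains fewer cycles than the protocol requires."""

    def __init__(self, found: int, required: int):
        self.found = found
        self.required = required
        super().__init__(
            f"detected {found} compression cycles, protocol requires {required}"
        )
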