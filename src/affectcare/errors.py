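"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A parameter violates a documented precondition."""


class DegenerateSignalError(ValueError):
    """A statistic is undefined for this signal (e.g. zero variance)."""


class NotFittedError(RuntimeError):
    """The model has not been trained yet."""
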