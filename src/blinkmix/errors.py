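"""Exception hierarchy for blinkmix."""


class BlinkmixError(Exception):
    """Base class for blinkmix-specific errors."""


class DegenerateModelError(BlinkmixError):
    """A mixture assigns zero probability to an observed blink count."""


class DegenerateDataError(BlinkmixError):
    """The data admit no valid parameter update (e.g. every blink count
    equals its assigned component size, so the M-step denominator is zero)."""


class SingularCorrectionError(BlinkmixError):
    """The labeling-correction system is singular for the given apparent
    weights and labeling efficiency."""
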