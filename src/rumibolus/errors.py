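"""Exception hierarchy for the bolus-accelerometer pipeline."""


class RumiBolusError(Exception):
    """Base class for all pipeline errors."""


class ParseError(RumiBolusError):
    """A file row could not be parsed (message carries the line number)."""


class GapError(RumiBolusError):
    """A sampling gap was found in a trace that must be uniformly sampled."""

    def __init__(self, message, gaps=None):
        super().__init__(message)
        #: list of (start_s, end_s) gap intervals, in seconds since trace start
        self.gaps = gaps or []


class ValidationError(RumiBolusError):
    """Input violates a structural contract (overlaps, bad classes, ...)."""


class InsufficientDataError(RumiBolusError):
    """Series shorter than the operation's minimum length."""


class NoElbowError(RumiBolusError):
    """Sensitivity curve has no detectable knee (constant or linear)."""


class InsufficientClassError(RumiBolusError):
    """A class has too few members for the requested split or fold count."""
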