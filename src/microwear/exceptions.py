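"""Exception hierarchy for the microwear package."""


class MicrowearError(Exception):
    """Base class for all package errors."""


class FormatError(MicrowearError, ValueError):
    """A file could not be parsed under the declared dialect."""


class ValidationError(MicrowearError, ValueError):
    """Input violates a documented precondition."""


class DegeneracyError(MicrowearError, ValueError):
    """Input is degenerate for the requested operation (e.g. collinear
    points for plane fitting, zero winsorized variance in a test group)."""
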