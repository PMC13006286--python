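"""Exception taxonomy shared across the package."""


class PreconditionError(ValueError):
    """An argument violated a documented precondition."""


class ProtocolError(ValueError):
    """The session protocol is malformed (e.g. class remainder not divisible)."""


class DataError(ValueError):
    """The supplied data cannot satisfy the request (e.g. too few shots)."""


class NumericError(FloatingPointError):
    """A degenerate numeric state (zero-norm vector, non-finite value)."""
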