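"""Exception types shared across the package."""


class InvrepError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(InvrepError, ValueError):
    """A search parameter violates its constraints (e.g. l > L, odd l in
    perfect mode, m = 0 in imperfect mode)."""


class FormatError(InvrepError, ValueError):
    """An input or report file does not conform to the expected format."""
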