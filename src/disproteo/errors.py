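"""Exception types shared across the package."""


class DisproteoError(Exception):
    """Base class for all package errors."""


class FormatError(DisproteoError, ValueError):
    """A file did not parse in the expected standard format."""


class ValidationError(DisproteoError, ValueError):
    """Parsed data violated a domain invariant."""


class BalanceError(DisproteoError, ValueError):
    """A reaction could not be balanced as requested."""
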