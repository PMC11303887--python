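"""Exceptions raised by the UCUM engine."""


class UcumError(ValueError):
    """Base class for UCUM engine errors."""


class ParseError(UcumError):
    """A unit code could not be parsed.

    Carries the character ``position`` at which parsing failed and a short
    ``reason`` (unknown atom, malformed exponent, empty component, ...).
    """

    def __init__(self, code: str, position: int, reason: str):
        self.code = code
        self.position = position
        self.reason = reason
        super().__init__(f"cannot parse {code!r} at position {position}: {reason}")


class SpecialUnitError(UcumError):
    """A nonlinear (special) unit such as Cel refuses linear conversion."""


class IncommensurableError(UcumError):
    """Two units have different dimension vectors and cannot be converted."""


class ArbitraryUnitError(UcumError):
    """Arbitrary units (e.g. [IU]) are commensurable only with themselves."""


class ProfileUnitError(UcumError):
    """The *expected* unit of a profile does not parse.

    This indicates a configuration fault in the profile, not a data
    discrepancy in the instance data.
    """
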