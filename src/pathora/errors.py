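"""Exception hierarchy shared across the package."""


class PathoraError(Exception):
    """Base class for all data/format errors raised by this package."""


class GpmlParseError(PathoraError):
    """Malformed XML or a document we cannot interpret."""


class UnsupportedDialectError(GpmlParseError):
    """XML whose root namespace is not a recognized GPML dialect."""


class GpmlValidationError(PathoraError):
    """A pathway violating model invariants (e.g. duplicate graph ids)."""


class TableFormatError(PathoraError):
    """A delimited text table missing required structure."""


class CriterionSyntaxError(PathoraError):
    """A criterion expression that does not parse.

    ``position`` is the 0-based character offset of the failure.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class CriterionTypeError(PathoraError):
    """A criterion applied to values of the wrong type."""


class CapabilityError(PathoraError):
    """An optional capability (e.g. PNG rasterization) is unavailable."""
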