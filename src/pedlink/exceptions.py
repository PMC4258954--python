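"""Exception hierarchy for pedlink."""


class PedlinkError(Exception):
    """Base class for all pedlink errors."""


class PedigreeStructureError(PedlinkError):
    """The pedigree graph is malformed (missing/half-specified parents, cycles)."""


class FileFormatError(PedlinkError):
    """A text input does not conform to its declared format.

    Carries ``line`` (1-based) when the offending line is known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class CapacityError(PedlinkError):
    """The pedigree exceeds the inheritance-vector bit ceiling."""


class ConfigurationError(PedlinkError):
    """An analysis or simulation configuration is invalid."""


class ParameterError(PedlinkError):
    """A function argument is outside its allowed range."""
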