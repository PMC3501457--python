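"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates an operation's precondition."""


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IntegrityError(ValueError):
    """A dataset violates a structural invariant (e.g. duplicate curve key)."""


class ConfigurationError(ValueError):
    """A configuration value is inconsistent (e.g. overlapping peak windows)."""


class NoInflectionError(RuntimeError):
    """No sign change of the second difference in the requested interval."""


class DegenerateFamilyError(RuntimeError):
    """All segment slopes identical; the q-on-k regression is vertical."""
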