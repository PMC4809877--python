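"""Exception hierarchy shared across the package."""


class SrnakitError(Exception):
    """Base class for all srnakit errors."""


class ParseError(SrnakitError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ValidationError(SrnakitError):
    """Input data violates a documented precondition or invariant."""


class ConfigurationError(SrnakitError):
    """A configuration value is out of range or infeasible."""
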