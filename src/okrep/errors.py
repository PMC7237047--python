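"""Exception hierarchy shared across the package."""


class OkrepError(Exception):
    """Base class for all package-specific errors."""


class ParseError(OkrepError, ValueError):
    """A file could not be parsed. Carries the 1-based line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ValidationError(OkrepError, ValueError):
    """Data violate a domain invariant (coordinates, strands, probabilities)."""


class ConfigError(OkrepError, ValueError):
    """A run configuration is inconsistent or incomplete."""
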