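"""Exception hierarchy.

Every error raised by the library derives from :class:`PoloscanError` and
carries a short machine-greppable ``code`` used by the CLI (one line on
stderr: ``<code>: <message>``).
"""


class PoloscanError(Exception):
    code = "E_GENERIC"


class MotifNotationError(PoloscanError, ValueError):
    """Malformed motif notation or invalid phosphoacceptor definition."""

    code = "E_MOTIF"


class WindowLengthError(PoloscanError, ValueError):
    code = "E_WINDOW"


class MatrixError(PoloscanError, ValueError):
    """Residue not representable in the substitution matrix."""

    code = "E_MATRIX"


class DomainError(PoloscanError, ValueError):
    """Arguments outside the mathematical domain of an operation."""

    code = "E_DOMAIN"


class ParseError(PoloscanError):
    """Malformed input file; carries the offending line number."""

    code = "E_PARSE"

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ConfigError(PoloscanError):
    """Invalid configuration; accumulates every violation before raising."""

    code = "E_CONFIG"

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))
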