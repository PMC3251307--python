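"""Exception hierarchy shared across the package."""


class GenomapError(Exception):
    """Base class for all data and project errors raised by genomap."""


class FormatError(GenomapError):
    """A track or table file violates its grammar.

    Carries the offending line number (1-based) when known so CLI users
    can locate the problem in community-edited files.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ProjectError(GenomapError):
    """A project directory is missing, unreadable or inconsistent."""
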