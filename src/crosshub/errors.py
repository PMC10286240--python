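"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: :class:`ConfigError` -> 2,
:class:`InputParseError` -> 3, :class:`StageError` -> 4.
"""

from __future__ import annotations


class CrosshubError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CrosshubError):
    """Invalid pipeline configuration (bad threshold, missing field, ...)."""


class InputParseError(CrosshubError):
    """Malformed input file; message carries the path and line number."""


class StageError(CrosshubError):
    """A pipeline stage failed; wraps the originating exception."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")


class DegenerateInputError(CrosshubError):
    """Input data carries no usable signal (e.g. zero variance everywhere)."""


class UndefinedScoreError(CrosshubError):
    """A score is mathematically undefined for the given arguments."""
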