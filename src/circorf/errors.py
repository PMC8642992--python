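"""Exception hierarchy.

User-facing errors all derive from :class:`CircOrfError` so the CLI can map
them to exit code 1; anything else is an internal error (exit code 2).
"""


class CircOrfError(Exception):
    """Base class for all circorf user errors."""


class ConfigurationError(CircOrfError):
    """Invalid simulation or pipeline configuration."""


class InputError(CircOrfError):
    """Malformed or inconsistent input data (names the offending record)."""


class DesignError(CircOrfError):
    """An assay design request that cannot be satisfied."""


class PipelineOrderError(CircOrfError):
    """A stage was invoked before the stage that produces its input."""
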