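"""Exception hierarchy.

User-facing errors (bad input files, inconsistent datasets, bad
configuration) derive from :class:`WingmorphError` so the CLI can map them
to exit code 1; anything else is treated as an internal error (exit 2).
"""


class WingmorphError(Exception):
    """Base class for all user-facing errors raised by wingmorph."""


class TPSParseError(WingmorphError):
    """A TPS file could not be parsed; message names the offending line."""


class DatasetError(WingmorphError):
    """A dataset violates an invariant (mixed landmark counts, duplicate IDs...)."""


class ConfigError(WingmorphError):
    """Invalid configuration or metadata table."""


class AnalysisError(WingmorphError):
    """A statistical routine received input it cannot handle."""


class StageError(WingmorphError):
    """Pipeline stage failure; wraps the original error with the stage name."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
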