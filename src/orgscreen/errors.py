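"""Exception hierarchy for orgscreen.

Config/schema problems and data problems are kept distinct so the CLI can
map them to different exit codes (2 for config, 1 for data).
"""


class OrgscreenError(Exception):
    """Base class for all orgscreen errors."""


class ConfigError(OrgscreenError):
    """Invalid configuration: bad thresholds, malformed layout, bad simulator parameters."""


class SchemaError(ConfigError):
    """A required column or key is missing or mistyped in an input table."""


class DataError(OrgscreenError):
    """Well-formed input whose values make a computation undefined."""


class DegenerateWellError(DataError):
    """Well signal at the first timepoint is non-positive; fold change undefined."""


class SlowGrowthError(DataError):
    """Negative-control fold change <= 1: GR/NDR normalization undefined.

    Carries ``fold_change`` so callers can report how slow the control grew.
    """

    def __init__(self, message: str, fold_change: float | None = None):
        super().__init__(message)
        self.fold_change = fold_change
        self.slow_growth = True
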