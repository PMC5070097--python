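"""Exception hierarchy shared across the pipeline stages."""


class TincError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TincError):
    """Invalid run or simulation configuration (exit code 2 at the CLI)."""


class InputFormatError(TincError):
    """Malformed input record or file (exit code 3 at the CLI)."""


class DuplicateReadError(InputFormatError):
    """More than two observations share one read identifier at a site."""


class PipelineError(TincError):
    """Inconsistent inputs reaching a stage (e.g. mismatched loci)."""


class EstimationError(TincError):
    """Contamination estimate is undefined for the given evidence."""
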