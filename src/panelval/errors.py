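"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigurationError -> 2, DataError
(including ParseError) -> 3, anything else -> 1.
"""


class PanelValError(Exception):
    """Base class for all panelval errors."""


class ConfigurationError(PanelValError):
    """Invalid configuration: bad parameter value, missing input path."""


class DataError(PanelValError):
    """Input data violates a contract (duplicates, contradictions)."""


class ParseError(DataError):
    """A file could not be parsed; message carries the line number."""
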