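"""Exception hierarchy used across the pipeline."""


class RangeshiftError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(RangeshiftError, ValueError):
    """A generator or model parameter is out of its valid domain."""


class SchemaError(RangeshiftError, ValueError):
    """Raster layers, variables or keys do not match the expected schema."""


class MissingDataError(RangeshiftError, ValueError):
    """Required inputs (years, key combinations) are absent; message lists gaps."""


class TooFewRecordsError(RangeshiftError, ValueError):
    """Fewer unique presence cells than the minimum needed to fit a model."""


class ConvergenceError(RangeshiftError, RuntimeError):
    """Optimizer hit its iteration cap before meeting the KKT tolerance."""


class NoHabitatError(RangeshiftError, ValueError):
    """A species' true range is empty; nothing to sample."""
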