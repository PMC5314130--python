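"""Exception hierarchy for covnet."""


class CovnetError(Exception):
    """Base class for all covnet errors."""


class ConfigurationError(CovnetError, ValueError):
    """Invalid configuration (bad parameter combinations, non-PSD targets, ...)."""


class InputValidationError(CovnetError, ValueError):
    """Input data violates the subject-volume-table contract."""


class DegenerateDataError(CovnetError, ValueError):
    """Data too degenerate for the requested operation (constant region,
    empty graph, fragmented network, zero-variance null, ...)."""
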