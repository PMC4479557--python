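"""Exception hierarchy."""


class EsalError(Exception):
    """Base class for all esal errors."""


class ConfigurationError(EsalError, ValueError):
    """Invalid run or generator configuration."""


class DataValidationError(EsalError, ValueError):
    """Input data violates a structural precondition (shape, sign, coverage)."""
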