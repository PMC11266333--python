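"""Exception types shared across the package."""


class PetBenchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PetBenchError, ValueError):
    """A scanner/digitiser/phantom configuration value is invalid."""


class AnalysisError(PetBenchError, ValueError):
    """An analysis precondition is violated (bad input data)."""
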