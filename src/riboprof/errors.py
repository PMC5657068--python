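"""Exception hierarchy shared across the pipeline."""


class RiboprofError(Exception):
    """Base class for all package errors."""


class ConfigError(RiboprofError):
    """Invalid configuration (bad paths, out-of-range parameters)."""


class DataError(RiboprofError):
    """Malformed or inconsistent input data."""


class ValidationError(DataError):
    """Annotation or record failed an invariant check."""
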