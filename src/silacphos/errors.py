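"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """Input data or configuration field failed validation."""


class ConfigurationError(ValueError):
    """Inconsistent or incomplete analysis configuration."""


class MappingError(ValueError):
    """A peptide could not be located in its assigned protein."""
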