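"""Exception types shared across the pipeline."""


class SchemaError(ValueError):
    """A required column is missing or the file layout is not recognised."""


class ParseError(ValueError):
    """A cell could not be parsed (e.g. non-numeric protein abundance)."""


class ValidationError(ValueError):
    """The parsed table violates a cohort invariant."""


class ConfigurationError(ValueError):
    """An analysis was requested with inconsistent or incomplete settings."""
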