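"""Exception hierarchy for pipeline validation failures."""


class PhenostatError(Exception):
    """Base class for all phenostat errors."""


class SchemaError(PhenostatError):
    """An input table is missing required columns or has the wrong shape."""


class ValidationError(PhenostatError):
    """An input value violates a documented invariant."""


class BijectionError(ValidationError):
    """The plant-ID / unit-coordinate translation is not one-to-one."""
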