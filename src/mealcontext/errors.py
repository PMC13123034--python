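"""Exception hierarchy shared across the pipeline."""


class MealContextError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MealContextError):
    """A required column is missing or a table cannot be parsed."""


class VocabularyError(MealContextError):
    """A categorical token is outside its controlled vocabulary."""


class ReferentialIntegrityError(MealContextError):
    """A row references an entity that does not exist."""


class InvariantError(MealContextError):
    """A row violates a domain invariant (range, exclusivity, ordering)."""


class EligibilityError(MealContextError):
    """A postprandial computation was requested for an ineligible meal."""


class ConfigError(MealContextError):
    """An analysis or simulation configuration is invalid."""


class SpecError(MealContextError):
    """A model specification is inconsistent with the data."""


class DegenerateDataError(MealContextError):
    """Input data are degenerate for the requested statistic."""
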