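"""Exception hierarchy used across the pipeline stages."""


class DietprintError(Exception):
    """Base class for all package errors."""


class DesignError(DietprintError):
    """Invalid survey design (counts, strata with too few PSUs, ...)."""


class MappingError(DietprintError):
    """Food-to-commodity mapping failure (unmapped food under strict policy)."""


class ConfigurationError(DietprintError):
    """Malformed parameter table, standard, or run configuration."""


class ScoringError(DietprintError):
    """Diet-index scoring cannot proceed (e.g. non-positive energy)."""


class EstimationError(DietprintError):
    """Design-based estimation failure (empty input, degenerate design)."""


class ModelError(DietprintError):
    """Biophysical model failure (e.g. a food group with no domestic member)."""
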