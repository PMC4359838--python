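"""Exception hierarchy for ltmclust.

All package-specific failures derive from :class:`LtmclustError` so callers
(and the CLI) can distinguish data problems from numerical ones.
"""


class LtmclustError(Exception):
    """Base class for all ltmclust errors."""


class SchemaError(LtmclustError):
    """Malformed input schema: duplicate/unknown column names, bad headers."""


class CodingError(LtmclustError):
    """A cell of a symptom matrix is not coded 0/1."""


class EmptySelectionError(LtmclustError):
    """A screening step removed every column."""


class ModelInvariantError(LtmclustError):
    """A latent tree model violates a structural or probabilistic invariant."""


class CapacityError(LtmclustError):
    """An exact enumeration would exceed the configured joint-size limit."""


class UndefinedPosteriorError(LtmclustError):
    """Posterior requested for evidence of probability zero."""


class DegenerateLatentError(LtmclustError):
    """A latent variable carries no information about the requested scope."""


class ConfigurationError(LtmclustError):
    """Inconsistent user configuration (factor maps, pipeline configs...)."""
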