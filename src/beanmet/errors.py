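"""Exception hierarchy shared across the package."""


class BeanmetError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BeanmetError):
    """A required column is missing or malformed in an input table."""


class DuplicateKeyError(BeanmetError):
    """More than one plot record shares a (genotype, environment, N, block) key."""


class DomainError(BeanmetError, ValueError):
    """An input value lies outside the physically meaningful domain."""


class DesignError(BeanmetError):
    """The experimental design cannot support the requested model term."""


class DegenerateChainError(BeanmetError):
    """An MCMC chain (or segment) has zero variance where variation is required."""


class InsufficientSamplesError(BeanmetError):
    """Too few draws/observations to compute the requested summary."""


class UsageError(BeanmetError):
    """Objects passed together are incompatible (different traits, levels, ...)."""


class ConfigError(BeanmetError):
    """A simulation or sampler configuration is internally inconsistent."""


class MissingCellError(BeanmetError):
    """A genotype x environment cell required to be populated is empty."""
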