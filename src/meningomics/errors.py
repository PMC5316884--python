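"""Exception hierarchy shared across the analysis stages."""


class MeningomicsError(Exception):
    """Base class for all package errors."""


class ValidationError(MeningomicsError, ValueError):
    """Malformed or out-of-range input (missing field, NaN likelihood, ...)."""


class ConfigurationError(MeningomicsError, ValueError):
    """Invalid configuration; the message names the offending field."""


class EstimationError(MeningomicsError, RuntimeError):
    """A statistical estimate could not be formed (e.g. no copy-loss segments)."""


class CoordinateError(MeningomicsError, ValueError):
    """A genomic interval falls outside the declared genome model."""


class DesignError(MeningomicsError, ValueError):
    """Confounded or degenerate model design (grade aliased with stratum, ...)."""


class DependencyError(MeningomicsError, RuntimeError):
    """A pipeline stage was enabled without the upstream output it requires."""
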