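"""Exception hierarchy shared across the package."""


class BlcasigError(Exception):
    """Base class for package-specific errors."""


class ConfigError(BlcasigError, ValueError):
    """Invalid simulation or pipeline configuration."""


class DomainError(BlcasigError, ValueError):
    """Input outside the documented domain of an operation."""


class FormatError(BlcasigError, ValueError):
    """Malformed input file (duplicate IDs, non-numeric cells, ragged rows)."""


class EmptyConsensusError(BlcasigError, RuntimeError):
    """No gene was ever selected across all resampling cycles."""
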