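"""Exception types shared across the package."""


class PhylostageError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(PhylostageError, ValueError):
    """Invalid simulation or analysis configuration."""


class FormatError(PhylostageError, ValueError):
    """A file or table violates the expected on-disk layout."""


class UndefinedCorrelationError(PhylostageError, ValueError):
    """A rank correlation is undefined (at least one vector is constant)."""


class CombinationCapError(PhylostageError, ValueError):
    """The stage-combination Cartesian product exceeds the configured cap."""


class NoCoveragePeakError(PhylostageError, ValueError):
    """A k-mer depth histogram has no coverage peak beyond the error mass."""
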