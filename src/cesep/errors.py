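"""Exception types shared across the package."""


class CesepError(Exception):
    """Base class for all package-specific errors."""


class InvalidPeakError(CesepError, ValueError):
    """A peak record violates its physical constraints (e.g. nonpositive width)."""


class MissingAnalyteError(CesepError, LookupError):
    """A requested analyte is absent from a peak table."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"analyte(s) not found in peak table: {', '.join(self.missing)}")


class SpectralCoverageError(CesepError, ValueError):
    """Spectra do not cover the requested comparison window."""


class DomainError(CesepError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DegenerateDesignError(CesepError, ValueError):
    """A regression design carries no usable information (e.g. one distinct x)."""


class RankDeficiencyError(CesepError, ValueError):
    """The model matrix is rank deficient for the requested fit or design."""

    def __init__(self, message, aliased=()):
        self.aliased = tuple(aliased)
        super().__init__(message)
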