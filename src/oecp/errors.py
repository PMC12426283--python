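"""Exception and warning types shared across the package."""


class OECPError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OECPError, ValueError):
    """An argument is outside the physical domain (e.g. non-positive frequency)."""


class ConfigurationError(OECPError, ValueError):
    """A configuration object is internally inconsistent.

    The message lists every violation found, not just the first.
    """


class SingularityError(OECPError, ArithmeticError):
    """The bilinear probe map is evaluated at (or inverted onto) its pole."""


class DegenerateStandardsError(OECPError, ValueError):
    """The three calibration standards do not determine the coefficients."""


class ExtractionInputError(OECPError, ValueError):
    """A displacement sweep is unusable for threshold extraction."""


class SummaryError(OECPError, ValueError):
    """No usable replicate values are available to summarize."""


class DegenerateVarianceError(OECPError, ValueError):
    """All observations are identical (or within-group variance is zero)."""


class IngestError(OECPError, ValueError):
    """A measured-sweep file violates the sweep CSV schema."""


class PhysicalityWarning(UserWarning):
    """An inverted permittivity lies outside the plausible range [1, 1000]."""
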