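"""Exception hierarchy shared across the package."""


class EqtlEnrichError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EqtlEnrichError, ValueError):
    """A delimited input file is structurally malformed (missing column,
    non-numeric field, ...)."""


class ValidationError(EqtlEnrichError, ValueError):
    """Input parsed but violates a domain invariant (MAF out of range,
    duplicate rsid, P-value outside (0, 1], inconsistent contingency table)."""


class ConfigError(EqtlEnrichError, ValueError):
    """A configuration value is invalid or internally inconsistent."""


class InfeasibleSampleError(EqtlEnrichError, ValueError):
    """The SNP universe cannot supply a requested MAF-matched null set."""
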