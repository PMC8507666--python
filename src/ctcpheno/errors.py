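"""Exception types for the CTC phenotyping pipeline."""


class CTCPhenoError(Exception):
    """Base class for all package errors."""


class FormatError(CTCPhenoError, ValueError):
    """A file or table violates the expected structure (missing columns,
    duplicate identifiers, wrong shape)."""


class ValidationError(CTCPhenoError, ValueError):
    """Values violate a domain invariant (negative TPM, non-positive
    survival time, probabilities outside [0, 1])."""


class MetadataError(CTCPhenoError, KeyError):
    """Required per-cell metadata is absent."""


class CardinalityError(CTCPhenoError, ValueError):
    """An operation received fewer items than it needs (empty stratum,
    fewer cells than clusters, empty cohort)."""


class DegenerateTableError(CTCPhenoError, ValueError):
    """A contingency table has a zero margin or is all-zero."""


class JoinError(CTCPhenoError, KeyError):
    """A cell or count refers to a patient absent from the clinical table."""


class ConfigurationError(CTCPhenoError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class EmptyCohortError(CardinalityError):
    """No cells survived QC; carries diagnostic counts."""

    def __init__(self, message: str, counts: dict | None = None):
        super().__init__(message)
        self.counts = dict(counts or {})
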