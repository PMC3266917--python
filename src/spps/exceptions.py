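"""Exception hierarchy for the spps package."""


class SPPSError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SPPSError):
    """Input data violates a documented contract (bad residue, short
    sequence, duplicate identifier, malformed table ...)."""


class UnknownProteinError(SPPSError, KeyError):
    """A protein id or entry name does not resolve in the database."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class CalibrationError(SPPSError):
    """Probability calibration cannot be performed (e.g. one class absent)."""


class FingerprintMismatchError(SPPSError):
    """A trained model's featurization fingerprint does not match the
    featurizer it is asked to predict with."""
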