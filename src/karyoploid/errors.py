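"""Exception hierarchy shared across the package."""


class KaryoploidError(Exception):
    """Base class for all package-specific errors."""


class InvalidMeasurementError(KaryoploidError, ValueError):
    """An arm length or channel value is non-positive, non-finite or malformed."""


class EmptyKaryotypeError(KaryoploidError, ValueError):
    """A karyotype-level operation received no chromosomes."""


class FitFailureError(KaryoploidError, RuntimeError):
    """A peak fit could not be computed (empty or degenerate window)."""


class UnresolvableSampleError(KaryoploidError, RuntimeError):
    """A flow histogram does not contain the two peaks needed for ratio-based
    genome-size estimation."""
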