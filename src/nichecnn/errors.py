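"""Exception types raised across the package."""


class NicheCNNError(Exception):
    """Base class for all package errors."""


class SchemaError(NicheCNNError):
    """A required column or config field is missing or malformed."""


class IntegrityError(NicheCNNError):
    """Input data violates a structural invariant (duplicate ids, an image
    spanning two samples, a sample spanning two conditions, ...)."""


class PreprocessError(NicheCNNError):
    """Invalid preprocessing request (already-preprocessed table, constant
    marker column, negative raw intensities)."""
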