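"""Exception hierarchy shared across the package."""


class MetaboMRError(Exception):
    """Base class for all package errors."""


class ValidationError(MetaboMRError):
    """A field or table violated an invariant; the message names the field."""


class FormatError(MetaboMRError):
    """A file could not be mapped onto the expected schema."""


class EstimationError(MetaboMRError):
    """An estimator could not produce a result (too few SNPs, degeneracy)."""
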