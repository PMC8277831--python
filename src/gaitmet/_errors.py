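"""Exception hierarchy shared across the package."""


class GaitmetError(Exception):
    """Base class for all package errors."""


class FormatError(GaitmetError):
    """A file does not conform to the expected on-disk layout."""


class DataError(GaitmetError):
    """Well-formed input whose contents violate an invariant (e.g. non-monotone time)."""


class ParameterError(GaitmetError, ValueError):
    """A caller-supplied parameter is out of its valid range."""


class FitError(GaitmetError):
    """A model fit could not be completed (degenerate design, non-convergence)."""


class StrideRejected(GaitmetError):
    """A stride cannot be converted to a feature row (too short, out of recording)."""
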