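"""Exception hierarchy shared across the package."""


class SalovlapError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SalovlapError):
    """A file is readable but not in the expected format (e.g. multi-channel mask)."""


class ValidationError(SalovlapError):
    """Input violates a stated invariant (duplicate ids, NaN values, bad labels...)."""


class ConsistencyError(SalovlapError):
    """Two inputs that must agree do not (e.g. saliency/mask shape mismatch)."""


class DegenerateInputError(SalovlapError):
    """The requested quantity is undefined for this input (e.g. Dice of two empty sets)."""


class ParameterError(SalovlapError):
    """Generator or run parameters are infeasible (e.g. lesion outside the breast)."""
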