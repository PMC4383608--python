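"""Exception hierarchy for contract, configuration and degenerate-input failures."""


class PiccsError(Exception):
    """Base class for all package-specific errors."""


class ContractViolationError(PiccsError, ValueError):
    """An operation was called with arguments violating its preconditions
    (shape mismatch, incompatible geometry, negative threshold, ...)."""


class ConfigurationError(PiccsError, ValueError):
    """A configuration value is outside its allowed range or unknown
    (bad filter name, invalid wavelet level count, ...)."""


class DegenerateInputError(PiccsError, ValueError):
    """Input is formally valid but degenerate for the requested quantity
    (all-zero sinogram for normalization, zero-mean ROI for CoV, ...)."""
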