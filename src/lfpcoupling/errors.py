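"""Exception hierarchy shared by all lfpcoupling modules."""


class LFPCouplingError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LFPCouplingError, ValueError):
    """An argument or configuration field is outside its valid domain."""


class DataError(LFPCouplingError, ValueError):
    """Input data violate a precondition (length, finiteness, coverage)."""


class FormatError(LFPCouplingError, ValueError):
    """An on-disk container is malformed or missing required metadata."""
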