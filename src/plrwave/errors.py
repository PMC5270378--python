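"""Exception hierarchy for pupillogram processing."""


class PLRError(ValueError):
    """Base class for all plrwave errors."""


class FormatError(PLRError):
    """Malformed on-disk input (missing columns, bad header, bad dialect)."""


class DataError(PLRError):
    """Structurally valid input whose contents violate a contract
    (non-monotone time, implausible diameters, incomplete subject...)."""


class ParameterError(PLRError):
    """Invalid parameter value passed to a simulation or analysis routine."""
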