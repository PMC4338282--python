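"""Exception hierarchy for segcpm."""


class SegCPMError(Exception):
    """Base class for all segcpm errors."""


class ConfigurationError(SegCPMError, ValueError):
    """A parameter or configuration value violates its documented contract."""


class ContractViolation(SegCPMError, ValueError):
    """An operation was called with arguments outside its precondition."""


class IntegrityError(SegCPMError, RuntimeError):
    """Internal bookkeeping (areas, labels) disagrees with the lattice."""


class UndefinedMeasureError(SegCPMError, ValueError):
    """A metric was requested on a state for which it is not defined."""
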