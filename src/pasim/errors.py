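"""Exception hierarchy."""


class PasimError(Exception):
    """Base class for all pasim errors."""


class ConfigurationError(PasimError):
    """Inconsistent or infeasible configuration (layout mismatch, bad budget)."""


class CapacityError(ConfigurationError):
    """Too many patterns for the network size (K*L must stay well below N)."""


class DegeneracyError(PasimError):
    """Pattern overlap matrix is singular or ill-conditioned."""


class ConsistencyError(PasimError):
    """Objects passed together were not derived from each other."""


class FormatError(PasimError):
    """Malformed serialized pattern set, bitmap or manifest."""
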