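"""Typed exceptions shared across the package."""


class ChemriskError(Exception):
    """Base class for all package errors."""


class ModelError(ChemriskError):
    """A Bayesian network or model file violates a structural invariant."""


class IncompleteAssignmentError(ChemriskError):
    """A joint-probability query did not assign every variable."""


class ZeroProbabilityEvidenceError(ChemriskError):
    """The supplied evidence has probability zero under the model."""


class OracleTooLargeError(ChemriskError):
    """The enumeration oracle was asked to sum over too large a state space."""


class TotalConflictError(ChemriskError):
    """Dempster combination attempted on fully conflicting mass functions (K=1)."""


class InsufficientDataError(ChemriskError):
    """EM was asked to fit from an empty case table."""


class ZeroProbabilityRecordError(ChemriskError):
    """A case record is impossible under the current parameters."""


class StructureMismatchError(ChemriskError):
    """Two networks expected to share a structure do not."""


class ConfigurationError(ChemriskError):
    """An analysis was configured inconsistently with the model."""
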