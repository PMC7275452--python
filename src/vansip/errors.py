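"""Exception hierarchy shared across the package."""


class VansipError(Exception):
    """Base class for all package-specific errors."""


class DomainError(VansipError, ValueError):
    """An input is outside the physically meaningful domain."""


class DegenerateInputError(VansipError, ValueError):
    """Input is formally valid but carries no usable signal (e.g. all-zero copies)."""


class PeakAssignmentError(VansipError, ValueError):
    """A density window cannot be populated with the required number of fractions."""


class PairingError(VansipError, ValueError):
    """A labeled sample lacks its paired unlabeled control."""


class InsufficientReplicationError(VansipError, ValueError):
    """Fewer replicates than the statistical test requires."""


class ConfigurationError(VansipError, ValueError):
    """Missing or inconsistent configuration (e.g. qPCR copies absent for a column)."""


class NoTransitionError(VansipError, RuntimeError):
    """The eigenvalue-spacing scan never settles on the Poisson side of the grid."""
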