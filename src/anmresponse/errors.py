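"""Exception hierarchy.

Everything the library raises on invalid input or an ill-posed model
derives from :class:`ANMError`, so callers (and the CLI) can catch one
type.
"""


class ANMError(Exception):
    """Base class for all domain errors raised by this package."""


class StructureError(ANMError):
    """The coarse-grained structure is malformed (no CA atoms, duplicates...)."""


class DisconnectedNetworkError(ANMError):
    """The spring network splits into more than one connected component."""


class DegeneracyError(ANMError):
    """The eigenproblem produced an unexpected number of zero-frequency modes."""


class CalibrationError(ANMError):
    """Spring-constant calibration is impossible (no experimental B-factors)."""


class RegimeError(ANMError):
    """The requested damping is outside the underdamped regime (xi >= 1)."""


class PairingError(ANMError):
    """Two conformations share too few residues to be superposed."""


class UndefinedOverlapError(ANMError):
    """Overlap requested against or with a zero-norm displacement vector."""
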