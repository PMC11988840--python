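"""Exception hierarchy for lamdiff."""


class LamdiffError(Exception):
    """Base class for all lamdiff analysis errors."""


class InputError(LamdiffError, ValueError):
    """Malformed or out-of-contract input data."""


class GeometryError(LamdiffError, ValueError):
    """Scattering geometry outside the valid range (angles, beam footprint)."""


class PeakFitError(LamdiffError, RuntimeError):
    """Bragg-peak fit failed to converge; carries residual diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientOrdersError(LamdiffError, ValueError):
    """Fewer than three diffraction orders: density reconstruction refused.

    Two diffraction orders do not provide enough resolution to constrain a
    centrosymmetric density profile and can produce misleading features.
    """


class PhaseError(LamdiffError, ValueError):
    """Phase-sign assignment is missing or inconsistent."""
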