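"""Exception hierarchy shared across the package.

Validation errors signal malformed or inconsistent inputs (CLI exit code 2);
computation errors signal failures inside an otherwise valid analysis
(CLI exit code 3).
"""


class CropChamberError(Exception):
    """Base class for all package errors."""


class ValidationError(CropChamberError, ValueError):
    """Input data or configuration violates a documented precondition."""


class ComputationError(CropChamberError, RuntimeError):
    """An analysis stage failed on valid-looking input."""


class DepletedIonError(ComputationError):
    """Nutrient uptake would drive a solution ion negative."""

    def __init__(self, ion: str, requested: float, available: float):
        self.ion = ion
        self.requested = requested
        self.available = available
        super().__init__(
            f"solution {ion} depleted: requested {requested:.4g} mol "
            f"but only {available:.4g} mol available"
        )
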