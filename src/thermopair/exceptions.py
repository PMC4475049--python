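"""Exception hierarchy shared across the package."""


class ThermopairError(Exception):
    """Base class for all package errors."""


class ValidationError(ThermopairError, ValueError):
    """Raised for invalid records, malformed tables or inconsistent inputs."""


class SchemaError(ValidationError):
    """Raised when a delimited input is missing mandatory columns."""


class EstimationError(ThermopairError):
    """Raised when a thermal-requirement estimate cannot be produced."""


class PairingError(ThermopairError):
    """Raised for invalid pairing inputs (duplicates, missing taxonomy)."""


class ConvergenceError(ThermopairError):
    """Raised when a mixed-model fit fails to converge."""
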