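"""Exception hierarchy shared across the package."""


class SpineImuError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SpineImuError, ValueError):
    """An argument violates a documented precondition."""


class SchemaError(SpineImuError, ValueError):
    """An input file does not match the expected column/key schema."""


class DataError(SpineImuError, ValueError):
    """Input data violates an integrity constraint (duplicates, non-finite, ...)."""


class InsufficientDataError(SpineImuError, ValueError):
    """A stream or track is too short for the requested operation."""


class GimbalLockError(SpineImuError, ValueError):
    """ZXY Euler extraction hit the |pitch| = 90 deg singularity.

    Attributes
    ----------
    beta_deg : float
        The degenerate pitch angle (+90 or -90 degrees).
    """

    def __init__(self, beta_deg: float):
        self.beta_deg = float(beta_deg)
        super().__init__(
            f"gimbal lock: pitch = {beta_deg:+.1f} deg, yaw/roll are not separable"
        )
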