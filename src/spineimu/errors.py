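"""Exception hierarchy shared across the pipeline stages.

Every error carries a short machine-readable ``code`` so the CLI can exit
with a stage-coded status.
"""


class SpineImuError(Exception):
    """Base class for all package errors."""

    code = 1


class FormatError(SpineImuError):
    """A delimited input file does not match the expected schema."""

    code = 10


class EmptyInputError(SpineImuError):
    """An input file or stream contains no usable rows."""

    code = 11


class ContractError(SpineImuError):
    """Arguments violate an interface contract (lengths, scopes, counts)."""

    code = 12


class UndefinedLagError(SpineImuError):
    """Cross-correlation cannot produce a meaningful lag (flat signal or
    sub-threshold correlation peak)."""

    code = 20


class InsufficientDataError(SpineImuError):
    """Too few valid checkpoints / rows to fit the requested model."""

    code = 21


class NoStillnessError(SpineImuError):
    """No stillness interval long enough for gyro-bias estimation."""

    code = 30


class ConfigurationError(SpineImuError):
    """Invalid or incomplete configuration."""

    code = 40


class MethodUnavailableError(SpineImuError):
    """A reference method cannot be computed from the available data."""

    code = 50

    def __init__(self, method: str, reason: str = ""):
        self.method = method
        msg = f"reference method {method!r} unavailable"
        if reason:
            msg += f": {reason}"
        super().__init__(msg)
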