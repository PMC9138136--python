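"""Exception hierarchy shared across the package."""


class BioreactError(Exception):
    """Base class for all package errors."""


class ConfigError(BioreactError):
    """Invalid or inconsistent configuration."""


class ScriptParseError(BioreactError):
    """A protocol script line could not be parsed.

    Carries the 1-based source line number and, when the opcode was
    recognised but its value was malformed, the offending field name.
    """

    def __init__(self, message: str, *, line_no: int, field: str | None = None):
        self.line_no = line_no
        self.field = field
        where = f"line {line_no}"
        if field:
            where += f", field {field}"
        super().__init__(f"{where}: {message}")


class ScriptRuntimeError(BioreactError):
    """Error raised while executing a protocol script."""

    def __init__(self, message: str, *, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class MaxStepsExceededError(ScriptRuntimeError):
    """Executed-instruction guard tripped (runaway Loop/Goto)."""


class DegenerateDesignError(BioreactError, ValueError):
    """A calibration fit was requested on a design with < 2 distinct levels."""


class CalibrationRangeError(BioreactError, ValueError):
    """A calibration pH level lies outside the phenol-red window."""


class VolumeRangeError(BioreactError, ValueError):
    """A volume outside (0, syringe capacity]."""


class OverdrawError(BioreactError):
    """Attempt to withdraw more media than a well or reservoir holds."""


class SyringeUnderflowError(BioreactError):
    """Attempt to dispense more than the syringe currently holds."""


class SyringeOverfillError(BioreactError):
    """Attempt to draw more than the syringe's remaining capacity."""
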