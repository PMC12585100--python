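"""Exception hierarchy shared across the package."""


class WbsleepError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WbsleepError, ValueError):
    """A file or table does not have the expected layout."""


class ShapeError(WbsleepError, ValueError):
    """Array dimensions are inconsistent with each other."""


class ParameterRangeError(WbsleepError, ValueError):
    """A derived model parameter left its admissible range."""


class DegenerateInputError(WbsleepError, ValueError):
    """An input is constant (or otherwise degenerate) where variation is required."""


class IntegrationDivergedError(WbsleepError, RuntimeError):
    """Numerical integration produced non-finite or inadmissible state."""


class PairingError(WbsleepError, ValueError):
    """Homotopic pairing of regions is incomplete or inconsistent."""


class ConvergenceError(WbsleepError, RuntimeError):
    """An iterative construction failed to reach its target."""
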