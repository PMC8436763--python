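"""Exception hierarchy for the flimca pipeline.

Every stage raises a subclass of :class:`FlimcaError` so callers (and the
scenario runner) can distinguish configuration mistakes from data-quality
failures.
"""


class FlimcaError(Exception):
    """Base class for all flimca errors."""


class ConfigurationError(FlimcaError):
    """Invalid parameter or geometry (caller bug, not a data problem)."""


class EmptyDesignError(ConfigurationError):
    """Population design with zero cells or zero boutons."""


class UndefinedNTCError(FlimcaError):
    """NTC cannot be formed (e.g. all-zero histogram)."""


class LowSignalError(FlimcaError):
    """Photon counts too low for a reliable lifetime readout."""


class CalibrationRangeError(FlimcaError):
    """NTC value outside the open asymptote interval of the calibration."""


class FitError(FlimcaError):
    """Calibration fit failed, refused (non-monotone), or under-determined."""


class SaturationError(FlimcaError):
    """Peak fluorescence at or beyond the saturation ceiling F_max."""


class BelowFloorError(FlimcaError):
    """Peak fluorescence at or below the Ca-free floor F_max / gamma."""


class QCError(FlimcaError):
    """A quality-control precondition failed for this recording."""


class PairingError(FlimcaError):
    """Before/after records cannot be matched by bouton id."""


class PipelineError(FlimcaError):
    """A scenario stage aborted; message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
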