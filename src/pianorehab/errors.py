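"""Exception types shared across the toolkit."""


class PianoRehabError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PianoRehabError, ValueError):
    """A file could not be parsed as an EMG recording / model container."""


class DataError(PianoRehabError, ValueError):
    """Input data violate a numeric precondition (NaN, negativity, ...)."""


class SimulationDivergedError(PianoRehabError, RuntimeError):
    """Forward dynamics produced a non-finite state.

    Attributes
    ----------
    last_valid_time : float
        Last simulation time (s) at which the state was finite.
    """

    def __init__(self, message: str, last_valid_time: float):
        super().__init__(message)
        self.last_valid_time = last_valid_time
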