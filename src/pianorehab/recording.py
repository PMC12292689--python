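"""In-memory container for multichannel surface-EMG recordings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = ["EMGRecording"]


@dataclass
class EMGRecording:
    """A multichannel sEMG time series.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in millivolts, one row per muscle channel.
    fs : float
        Sampling rate in Hz, > 0.
    channel_names : list of str
        One label per channel (e.g. ``["ED", "FDS", "ECU", "FCU"]``).
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("recording contains non-finite samples")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs
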