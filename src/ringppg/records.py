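"""Core PPG time-series container shared by the signal-path modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PPGRecord"]


@dataclass
class PPGRecord:
    """A single-channel PPG time series in linear (ADC-like) units.

    ``fs`` is the sampling rate in Hz (ring devices in this class sample at
    100 Hz); ``channel_label`` identifies the LED/PD channel.
    """

    samples: np.ndarray
    fs: float
    channel_label: str = "ch0"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs
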