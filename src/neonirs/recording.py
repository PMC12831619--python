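"""Raw continuous-wave recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import ProbeLayout
from .optics import WAVELENGTHS


@dataclass(frozen=True)
class Event:
    time: float  # s
    label: str


@dataclass
class RawRecording:
    """Two-wavelength intensity time series with events and geometry.

    intensity : (time, channel, 2) array, arbitrary detector units, > 0;
        last axis ordered as (780, 850) nm.
    fs : sampling rate in Hz (default 10).
    events : trial-onset markers carrying condition/phase labels.
    """

    intensity: np.ndarray
    fs: float
    events: list[Event]
    layout: ProbeLayout
    wavelengths: tuple[float, float] = WAVELENGTHS

    def __post_init__(self) -> None:
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise ValueError("intensity must be (time, channel, 2)")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity <= 0):
            raise ValueError("intensity must be finite and strictly positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        span = self.intensity.shape[0] / self.fs
        for ev in self.events:
            if not 0 <= ev.time <= span:
                raise ValueError(f"event at {ev.time} s outside recording span")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs
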