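"""Windowed channel-quality screening (scalp coupling index / peak
spectral power) and the dataset inclusion rule.

A channel whose optodes couple well to the scalp carries the cardiac
pulsation coherently on both wavelengths. Per non-overlapping window the
two wavelength signals are band-passed to the infant heart-rate band and
standardised; the scalp coupling index (SCI) is their zero-lag Pearson
correlation and the peak spectral power (PSP) is the peak of the power
spectrum of their normalised cross-correlation (a pure shared sinusoid
yields PSP near 1). A window passes iff SCI >= 0.7 and PSP >= 0.1; a
channel is flagged when fewer than 70% of its windows pass; a dataset is
excluded when more than 40% of channels are flagged (more than seven of
the 18-channel array).

Screening runs on raw intensity, before any correction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .recording import RawRecording


@dataclass(frozen=True)
class QualityParams:
    cardiac_band: tuple[float, float] = (1.5, 3.5)  # Hz, infant heart rate
    sci_threshold: float = 0.7
    psp_threshold: float = 0.1
    window_length: float = 5.0  # s, non-overlapping
    required_pass_fraction: float = 0.70
    max_flagged_fraction: float = 0.40

    def validate(self, fs: float) -> None:
        lo, hi = self.cardiac_band
        if not 0 < lo < hi < fs / 2:
            raise ValueError("cardiac band must satisfy 0 < low < high < fs/2")
        if not -1 <= self.sci_threshold <= 1 or self.psp_threshold < 0:
            raise ValueError("invalid SCI/PSP thresholds")
        if not 0 < self.required_pass_fraction <= 1:
            raise ValueError("required_pass_fraction must be in (0, 1]")
        if not 0 <= self.max_flagged_fraction <= 1:
            raise ValueError("max_flagged_fraction must be in [0, 1]")


@dataclass
class ChannelQualityReport:
    sci: np.ndarray  # (channel, window)
    psp: np.ndarray  # (channel, window)
    window_pass: np.ndarray  # (channel, window) bool
    pass_fraction: np.ndarray  # (channel,)
    flagged: np.ndarray  # (channel,) bool
    params: QualityParams

    @property
    def n_channels(self) -> int:
        return len(self.flagged)

    @property
    def flagged_count(self) -> int:
        return int(self.flagged.sum())

    @property
    def included(self) -> bool:
        return dataset_inclusion(self)[0]

    def good_channel_mask(self) -> np.ndarray:
        return ~self.flagged

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": np.arange(1, self.n_channels + 1),
                "pass_fraction": self.pass_fraction,
                "flagged": self.flagged,
            }
        )

    def to_json(self, path) -> None:
        included, reason = dataset_inclusion(self)
        payload = {
            "pass_fraction": self.pass_fraction.tolist(),
            "flagged": self.flagged.astype(bool).tolist(),
            "flagged_count": self.flagged_count,
            "included": included,
            "reason": reason,
            "sci_threshold": self.params.sci_threshold,
            "psp_threshold": self.params.psp_threshold,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _window_sci_psp(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """SCI and PSP for one pair of standardised cardiac-band windows."""
    n = len(x)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0, 0.0
    x = (x - x.mean()) / sx
    y = (y - y.mean()) / sy
    sci = float(np.dot(x, y) / n)
    # Normalised cross-correlation on lags |k| <= n/2 with unbiased
    # scaling, so a pure shared sinusoid gives a unit-amplitude cosine
    # sequence and hence PSP near 1.
    half = n // 2
    full = sps.correlate(x, y, mode="full") / n
    lags = np.arange(-(n - 1), n)
    keep = np.abs(lags) <= half
    xc = full[keep] / (1.0 - np.abs(lags[keep]) / n)
    m = len(xc)
    amp = 2.0 * np.abs(np.fft.rfft(xc)) / m
    psp = float(np.max(amp**2))
    return sci, psp


def windowed_sci_psp(
    rec: RawRecording, params: QualityParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel, per-window (SCI, PSP) on raw intensity.

    Returns two (n_channels, n_windows) arrays.
    """
    params = params or QualityParams()
    params.validate(rec.fs)
    win = int(round(params.window_length * rec.fs))
    n_win = rec.n_samples // win
    if n_win < 1:
        raise ValueError("recording shorter than one QC window")

    sos = sps.butter(3, params.cardiac_band, btype="bandpass", fs=rec.fs, output="sos")
    filt = sps.sosfiltfilt(sos, rec.intensity, axis=0)

    sci = np.empty((rec.n_channels, n_win))
    psp = np.empty((rec.n_channels, n_win))
    for c in range(rec.n_channels):
        for w in range(n_win):
            seg = slice(w * win, (w + 1) * win)
            sci[c, w], psp[c, w] = _window_sci_psp(filt[seg, c, 0], filt[seg, c, 1])
    return sci, psp


def flag_channels(
    metrics: tuple[np.ndarray, np.ndarray], params: QualityParams | None = None
) -> ChannelQualityReport:
    """Flag channels failing SCI/PSP on more than 30% of windows."""
    params = params or QualityParams()
    sci, psp = metrics
    if sci.size == 0:
        raise ValueError("empty quality metrics")
    window_pass = (sci >= params.sci_threshold) & (psp >= params.psp_threshold)
    pass_fraction = window_pass.mean(axis=1)
    flagged = pass_fraction < params.required_pass_fraction
    return ChannelQualityReport(sci, psp, window_pass, pass_fraction, flagged, params)


def dataset_inclusion(report: ChannelQualityReport) -> tuple[bool, str]:
    """Dataset included iff flagged channels <= floor(40% of channels)."""
    limit = math.floor(report.params.max_flagged_fraction * report.n_channels)
    count = report.flagged_count
    if count <= limit:
        return True, f"{count} flagged channel(s) <= limit {limit}"
    return False, f"{count} flagged channel(s) > limit {limit}"


def assess_recording(
    rec: RawRecording, params: QualityParams | None = None
) -> ChannelQualityReport:
    """Convenience: windowed metrics + channel flagging in one call."""
    params = params or QualityParams()
    return flag_channels(windowed_sci_psp(rec, params), params)
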