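"""Activation-paradigm preprocessing: raw intensity to epoched Hb.

Chain (each stage bypassable for ablation):
intensity -> optical density -> spline motion correction (p = 0.99)
-> wavelet denoising (IQR factor 0.8) -> zero-phase low-pass (0.6 Hz)
-> modified Beer-Lambert inversion (DPF 5.22 / 4.23) -> [-2, 18] s
epochs baseline-corrected on [-2, 0] s, with trial- and subject-level
validity rules (minimum three valid trials per required condition).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy.interpolate import make_smoothing_spline

from .optics import OpticalConstants, od_to_hb_arrays
from .quality import ChannelQualityReport
from .recording import RawRecording
from .schedule import StimulusSchedule


@dataclass(frozen=True)
class PreprocessParams:
    spline_smoothing: float = 0.99  # MATLAB-style p of the smoothing spline
    wavelet_iqr: float = 0.8  # IQR multiplier alpha for coefficient rejection
    lowpass_cutoff: float = 0.6  # Hz
    optics: OpticalConstants = field(default_factory=OpticalConstants)
    epoch_window: tuple[float, float] = (-2.0, 18.0)  # s relative to onset
    baseline_window: tuple[float, float] = (-2.0, 0.0)  # s
    min_trials: int = 3
    motion_sd_multiplier: float = 5.0  # moving-SD detection threshold
    motion_amp_threshold: float = 0.01  # OD units; absolute floor so smooth
    # noise-free hemodynamics are never mistaken for motion
    motion_window: float = 1.0  # s
    motion_overlap_fraction: float = 0.5  # trial invalid above this
    wavelet: str = "db2"

    def __post_init__(self) -> None:
        if not 0 < self.spline_smoothing <= 1:
            raise ValueError("spline_smoothing must be in (0, 1]")
        if self.min_trials < 1:
            raise ValueError("min_trials must be >= 1")
        ew, bw = self.epoch_window, self.baseline_window
        if not (ew[0] <= bw[0] and bw[1] <= ew[1]):
            raise ValueError("epoch_window must contain baseline_window")


@dataclass
class HbTimeSeries:
    """Continuous HbO/HbR (time x channel, uM change) with channel mask."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    valid_channel_mask: np.ndarray

    def __post_init__(self) -> None:
        if len(self.valid_channel_mask) != self.hbo.shape[1]:
            raise ValueError("mask length must equal channel count")


@dataclass
class EpochSet:
    """Baseline-corrected per-trial responses (trial x channel x time, uM)."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    times: np.ndarray  # s relative to onset
    condition: list[str]
    phase: list[str | None]
    trial_valid: np.ndarray
    valid_channel_mask: np.ndarray
    subject_valid: dict[str, bool] = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.hbo.shape[0]

    def trial_indices(self, label: str, valid_only: bool = True) -> np.ndarray:
        """Trials whose condition or phase equals ``label``."""
        match = np.array(
            [c == label or p == label for c, p in zip(self.condition, self.phase)]
        )
        if valid_only:
            match &= self.trial_valid
        return np.flatnonzero(match)

    def condition_mean(self, label: str, chromophore: str = "hbo") -> np.ndarray:
        """Trial-averaged (channel x time) response for one label."""
        idx = self.trial_indices(label)
        if len(idx) == 0:
            raise ValueError(f"no valid trials for {label!r}")
        data = self.hbo if chromophore == "hbo" else self.hbr
        return data[idx].mean(axis=0)


def intensity_to_od(rec: RawRecording) -> np.ndarray:
    """Optical density -log10(I / mean_t I), per channel and wavelength."""
    if np.any(rec.intensity <= 0):
        raise ValueError("intensity must be strictly positive")
    ref = rec.intensity.mean(axis=0, keepdims=True)
    return -np.log10(rec.intensity / ref)


def detect_motion_segments(
    series: np.ndarray, fs: float, params: PreprocessParams | None = None
) -> list[tuple[int, int]]:
    """Per-recording motion segments from a moving-SD rule.

    A sample is motion-suspect on a channel when the 1 s moving SD
    exceeds ``motion_sd_multiplier`` times that channel's median moving
    SD; suspect samples on any channel are merged into [start, stop)
    segments (samples).
    """
    params = params or PreprocessParams()
    n = series.shape[0]
    win = max(2, int(round(params.motion_window * fs)))
    kernel = np.ones(win) / win
    x = series.reshape(n, -1)
    mean = np.apply_along_axis(lambda v: np.convolve(v, kernel, "same"), 0, x)
    sq = np.apply_along_axis(lambda v: np.convolve(v, kernel, "same"), 0, x**2)
    sd = np.sqrt(np.maximum(sq - mean**2, 0))
    med = np.median(sd, axis=0, keepdims=True)
    suspect = (
        (sd > params.motion_sd_multiplier * np.maximum(med, 1e-12))
        & (sd > params.motion_amp_threshold)
    ).any(axis=1)
    # dilate by half a window so segments cover the artifact's support
    pad = win // 2
    idx = np.flatnonzero(suspect)
    dilated = np.zeros(n, dtype=bool)
    for i in idx:
        dilated[max(0, i - pad) : min(n, i + pad + 1)] = True
    segments = []
    i = 0
    while i < n:
        if dilated[i]:
            j = i
            while j < n and dilated[j]:
                j += 1
            segments.append((i, j))
            i = j
        else:
            i += 1
    return segments


def motion_spline_correct(
    od: np.ndarray,
    fs: float,
    params: PreprocessParams | None = None,
    segments: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Spline-based motion correction within detected segments.

    Within each flagged segment a smoothing spline (MATLAB-style
    smoothing parameter p, here lam = (1-p)/p) is fitted and subtracted;
    the segment is re-anchored to the preceding sample and the remainder
    of the series is shifted to preserve continuity at the segment end
    (so baseline shifts are removed, not just smoothed). Identity when
    nothing is detected.
    """
    params = params or PreprocessParams()
    if segments is None:
        segments = detect_motion_segments(od, fs, params)
    if not segments:
        return od.copy()
    lam = (1.0 - params.spline_smoothing) / params.spline_smoothing
    out = od.copy()
    flat = out.reshape(out.shape[0], -1)
    n = flat.shape[0]
    for a, b in segments:
        b = min(b, n)
        if b - a < 5:
            continue
        t = np.arange(a, b, dtype=float)
        for c in range(flat.shape[1]):
            seg = flat[a:b, c]
            spline = make_smoothing_spline(t, seg, lam=lam)(t)
            resid = seg - spline
            anchor = flat[a - 1, c] if a > 0 else spline[0]
            corrected = resid + anchor
            if b < n:
                flat[b:, c] += (corrected[-1] + (spline[-1] - spline[-2])) - flat[b, c]
            flat[a:b, c] = corrected
    return out


def fs_ratio(params: "PreprocessParams", fs: float = 10.0) -> float:
    """Ratio setting the wavelet depth: detail bands end where the
    retained hemodynamic band (the low-pass cutoff) begins."""
    return fs / (2.0 * params.lowpass_cutoff)


def wavelet_denoise(
    od: np.ndarray, params: PreprocessParams | None = None, fs: float = 10.0
) -> np.ndarray:
    """Wavelet motion-artifact rejection.

    Multilevel DWT per channel; detail coefficients outside
    [Q1 - alpha*IQR, Q3 + alpha*IQR] are zeroed; reconstruct. The
    decomposition depth is chosen so the approximation band contains the
    hemodynamic band retained by the subsequent low-pass (details only
    span higher frequencies), so outlier rejection removes transients
    without clipping evoked-response structure. Levels whose coefficient
    IQR is zero (degenerate, e.g. exactly flat baselines) are skipped.
    """
    params = params or PreprocessParams()
    n = od.shape[0]
    level = max(1, int(np.ceil(np.log2(fs_ratio(params, fs)))))
    max_level = pywt.dwt_max_level(n, params.wavelet)
    if level > max_level:
        warnings.warn("series short for requested wavelet depth; reducing")
        level = max(1, max_level)
    out = np.empty_like(od)
    flat_in = od.reshape(n, -1)
    flat_out = out.reshape(n, -1)
    for c in range(flat_in.shape[1]):
        coeffs = pywt.wavedec(flat_in[:, c], params.wavelet, level=level)
        for d in range(1, len(coeffs)):
            cd = coeffs[d]
            q1, q3 = np.percentile(cd, [25, 75])
            iqr = q3 - q1
            if iqr == 0:
                continue
            lo, hi = q1 - params.wavelet_iqr * iqr, q3 + params.wavelet_iqr * iqr
            coeffs[d] = np.where((cd < lo) | (cd > hi), 0.0, cd)
        flat_out[:, c] = pywt.waverec(coeffs, params.wavelet)[:n]
    return out


def lowpass_filter(series: np.ndarray, fs: float, cutoff: float = 0.6) -> np.ndarray:
    """Zero-phase Butterworth low-pass (order 5, forward-backward)."""
    if not 0 < cutoff < fs / 2:
        raise ValueError("cutoff must satisfy 0 < cutoff < fs/2")
    sos = sps.butter(5, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, series, axis=0)


def od_to_hb(
    od: np.ndarray,
    fs: float,
    optics: OpticalConstants | None = None,
    valid_channel_mask: np.ndarray | None = None,
) -> HbTimeSeries:
    """Invert the modified Beer-Lambert law; output uM."""
    optics = optics or OpticalConstants()
    hbo, hbr = od_to_hb_arrays(od, optics)
    if valid_channel_mask is None:
        valid_channel_mask = np.ones(od.shape[1], dtype=bool)
    return HbTimeSeries(hbo, hbr, fs, np.asarray(valid_channel_mask, dtype=bool))


def epoch_and_validate(
    hb: HbTimeSeries,
    schedule: StimulusSchedule,
    qc: ChannelQualityReport | None = None,
    params: PreprocessParams | None = None,
    motion_segments: list[tuple[int, int]] | None = None,
) -> EpochSet:
    """Cut baseline-corrected trial epochs and apply validity rules.

    A trial is invalid if its epoch extends past the recording or if a
    detected motion segment overlaps its epoch on more than 50% of valid
    channels (the moving-SD detector runs per channel, so overlap is
    assessed per channel). Subject validity: >= 3 valid trials for each
    of N and V (social) and for each of Fam1 and Fam3 (hand).
    """
    params = params or PreprocessParams()
    if schedule.n_trials == 0:
        raise ValueError("schedule has no trials")
    fs = hb.fs
    w0, w1 = params.epoch_window
    b0, b1 = params.baseline_window
    n_off = int(round(w0 * fs))
    n_len = int(round((w1 - w0) * fs)) + 1
    times = w0 + np.arange(n_len) / fs
    bmask = (times >= b0) & (times < b1)
    if not bmask.any():
        bmask = times <= b1

    mask = qc.good_channel_mask() if qc is not None else hb.valid_channel_mask
    mask = mask & hb.valid_channel_mask
    n_ch = hb.hbo.shape[1]
    n_samp = hb.hbo.shape[0]

    if motion_segments is None:
        motion_segments = []
    motion_per_channel = np.zeros((n_samp, n_ch), dtype=bool)
    for a, b in motion_segments:
        motion_per_channel[a:b, :] = True

    hbo = np.full((schedule.n_trials, n_ch, n_len), np.nan)
    hbr = np.full_like(hbo, np.nan)
    valid = np.zeros(schedule.n_trials, dtype=bool)
    for i, tr in enumerate(schedule.trials):
        start = int(round(tr.onset * fs)) + n_off
        stop = start + n_len
        if start < 0 or stop > n_samp:
            continue
        e_hbo = hb.hbo[start:stop].T.copy()  # (ch, time)
        e_hbr = hb.hbr[start:stop].T.copy()
        e_hbo -= e_hbo[:, bmask].mean(axis=1, keepdims=True)
        e_hbr -= e_hbr[:, bmask].mean(axis=1, keepdims=True)
        hbo[i], hbr[i] = e_hbo, e_hbr
        overlap = motion_per_channel[start:stop][:, mask].any(axis=0)
        frac = overlap.mean() if overlap.size else 0.0
        valid[i] = frac <= params.motion_overlap_fraction
    hbo[:, ~mask, :] = np.nan  # flagged channels carry no data
    hbr[:, ~mask, :] = np.nan

    epochs = EpochSet(
        hbo=hbo,
        hbr=hbr,
        fs=fs,
        times=times,
        condition=schedule.conditions(),
        phase=schedule.phases(),
        trial_valid=valid,
        valid_channel_mask=mask,
    )
    m = params.min_trials
    if schedule.paradigm == "social":
        epochs.subject_valid["social"] = (
            len(epochs.trial_indices("N")) >= m and len(epochs.trial_indices("V")) >= m
        )
    elif schedule.paradigm == "hand":
        epochs.subject_valid["hand"] = (
            len(epochs.trial_indices("Fam1")) >= m
            and len(epochs.trial_indices("Fam3")) >= m
        )
    return epochs


def preprocess_recording(
    rec: RawRecording,
    schedule: StimulusSchedule,
    qc: ChannelQualityReport | None = None,
    params: PreprocessParams | None = None,
    *,
    spline: bool = True,
    wavelet: bool = True,
    lowpass: bool = True,
) -> EpochSet:
    """Full chain: OD -> spline -> wavelet -> low-pass -> MBLL -> epochs."""
    params = params or PreprocessParams()
    od = intensity_to_od(rec)
    segments = detect_motion_segments(od, rec.fs, params)
    if spline:
        od = motion_spline_correct(od, rec.fs, params, segments)
    if wavelet:
        od = wavelet_denoise(od, params, rec.fs)
    if lowpass:
        od = lowpass_filter(od, rec.fs, params.lowpass_cutoff)
    hb = od_to_hb(od, rec.fs, params.optics)
    return epoch_and_validate(hb, schedule, qc, params, motion_segments=segments)
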