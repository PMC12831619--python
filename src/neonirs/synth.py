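"""Synthetic-subject generator with known ground truth.

Emulates the sleeping-infant acquisition: block-design hemodynamic
responses with condition/epoch-specific amplitudes (vocal vs nonvocal
selectivity, habituation decay across five-trial epochs), slow-band
inter-regional correlation structure for the connectivity paradigm,
physiological noise (cardiac, respiratory, vasomotor, 1/f drift, white),
motion artifacts (spikes and baseline shifts), and good/bad-coupling
channels, rendered to raw two-wavelength intensities through a forward
Beer-Lambert model.

Hemodynamics are built from a double-gamma HRF convolved with each
trial's boxcar and normalised so the planted amplitude equals the peak
HbO excursion in micromolar. HbR mirrors HbO with opposite sign, a
configurable ratio and a short lag — only the sign and rough magnitude
matter for the contrast-gating logic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.stats import gamma as gamma_dist

from .layout import ProbeLayout, ROI_ORDER, build_probe_layout
from .optics import OpticalConstants, hb_to_od
from .recording import Event, RawRecording
from .schedule import StimulusSchedule, build_schedule

# Physiological noise amplitudes (uM). Spontaneous slow hemodynamic
# fluctuations in infant recordings are comparable to evoked responses
# (which is why trial averaging is needed at all), so the drift and
# vasomotor terms sit at the ~0.3-1 uM scale of a ~1 uM response.
DEFAULT_NOISE = {
    "cardiac": 0.15,  # shared cardiac oscillation (coupling basis of SCI)
    "respiratory": 0.20,  # ~0.7 Hz
    "vasomotor": 0.30,  # ~0.1 Hz Mayer-wave band
    "drift": 0.80,  # 1/f low-frequency drift, per channel
    "white": 0.05,  # per-sample detector noise
}


@dataclass
class GroundTruth:
    """Planted generative parameters for one synthetic subject.

    amplitude_map maps a condition or epoch label (``"N"``, ``"V"``,
    ``"Fam1"`` ...) to a per-channel array of peak HbO amplitudes in uM.
    region_correlation is the 4x4 target slow-band ROI correlation
    matrix in the fixed (LF, LT, RF, RT) order.
    """

    amplitude_map: dict[str, np.ndarray] = field(default_factory=dict)
    hrf_peak_time: float = 7.0  # s
    hrf_undershoot_ratio: float = 1.0 / 6.0
    hbr_ratio: float = 1.0 / 3.0
    hbr_lag: float = 0.5  # s
    region_correlation: np.ndarray = field(default_factory=lambda: np.eye(4))
    # uM RMS of each region latent; sized so the shared regional signal
    # dominates ROI averages over per-channel drift, matching the
    # correlation magnitudes resting infant recordings actually show
    fc_amplitude: float = 0.8
    fc_band: tuple[float, float] = (0.01, 0.08)  # Hz
    artifact_events: list[tuple[float, str, float]] = field(default_factory=list)
    bad_channels: frozenset[int] = frozenset()  # channel ids (1-based)
    noise_params: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE))
    cardiac_freq: float = 2.3  # Hz, within the infant heart-rate band
    seed: int = 0

    def __post_init__(self) -> None:
        C = np.asarray(self.region_correlation, dtype=float)
        if C.shape != (4, 4) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1):
            raise ValueError("region_correlation must be symmetric 4x4 with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("region_correlation must be positive semi-definite")
        if not 1.5 <= self.cardiac_freq <= 3.5:
            raise ValueError("cardiac_freq outside the infant band [1.5, 3.5] Hz")
        for v in self.amplitude_map.values():
            if not np.all(np.isfinite(v)):
                raise ValueError("amplitudes must be finite")


@dataclass
class HbSubject:
    """Hemoglobin-domain time series for one subject (time x channel, uM)."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    schedule: StimulusSchedule
    layout: ProbeLayout
    truth: GroundTruth


def double_gamma_hrf(
    t: np.ndarray, peak_time: float = 7.0, undershoot_ratio: float = 1.0 / 6.0
) -> np.ndarray:
    """Canonical double-gamma HRF, peak normalised to 1."""
    main = gamma_dist.pdf(t, 6.0, scale=peak_time / 5.0)
    under = gamma_dist.pdf(t, 16.0, scale=(peak_time + 9.0) / 15.0)
    h = main / main.max() - undershoot_ratio * under / under.max()
    return h / h.max()


def trial_response(
    fs: float, duration: float, peak_time: float, undershoot_ratio: float, length: int
) -> np.ndarray:
    """Boxcar-convolved HRF for one trial, peak normalised to 1, uM/uM."""
    t = np.arange(length) / fs
    hrf = double_gamma_hrf(t, peak_time, undershoot_ratio)
    box = np.ones(max(1, int(round(duration * fs))))
    resp = np.convolve(hrf, box)[:length]
    return resp / resp.max()


def _bandlimited_noise(rng, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` (Hz).

    Synthesised in the frequency domain (random phase/amplitude on the
    in-band bins only), which stays stationary where a very narrow
    time-domain filter would be dominated by edge transients.
    """
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.zeros(len(f), dtype=complex)
    inband = (f >= band[0]) & (f <= band[1])
    k = int(inband.sum())
    if k == 0:
        raise ValueError("band contains no Fourier bins at this duration")
    spec[inband] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    y = np.fft.irfft(spec, n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _correlated_latents(rng, n: int, fs: float, band, C: np.ndarray) -> np.ndarray:
    """Four band-limited series whose *sample* correlation equals C.

    Independent band-limited draws are orthonormalised (QR) and mixed
    with the Cholesky factor, so the planted matrix is realised exactly
    rather than only in expectation.
    """
    L = np.linalg.cholesky(np.asarray(C, dtype=float) + 1e-12 * np.eye(4))
    Z = np.column_stack([_bandlimited_noise(rng, n, fs, band) for _ in range(4)])
    Z -= Z.mean(axis=0)
    Q, _ = np.linalg.qr(Z)
    Q /= Q.std(axis=0, keepdims=True)
    return Q @ L.T  # (n, 4), unit variance, corr = C


def _one_over_f(rng, n: int, fs: float = 10.0, fmax: float = 0.5) -> np.ndarray:
    """Unit-variance low-frequency drift: 1/f-amplitude spectrum limited
    to below ``fmax`` Hz (slow vascular drift has no cardiac-band power)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1.0 / fs)
    f[0] = f[1] if n > 1 else 1.0
    shape = np.where(f <= fmax, 1.0 / np.sqrt(f), 0.0)
    shaped = np.fft.irfft(spec * shape, n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def simulate_subject(
    layout: ProbeLayout,
    schedule: StimulusSchedule,
    truth: GroundTruth,
    *,
    fs: float = 10.0,
    tail: float = 20.0,
) -> HbSubject:
    """Clean (noise-free) HbO/HbR responses per channel.

    HbO is the sum over trials of the planted amplitude times the
    boxcar-convolved HRF; HbR = -hbr_ratio * HbO delayed by hbr_lag.
    For the fc paradigm, four band-limited latent region signals with
    the planted correlation matrix are added to their region's channels.
    """
    n = int(round((schedule.total_duration + tail) * fs))
    n_ch = layout.n_channels
    hbo = np.zeros((n, n_ch))
    rng = np.random.default_rng(truth.seed)

    for tr in schedule.trials:
        key = tr.phase if tr.phase is not None else tr.condition
        amps = truth.amplitude_map.get(key)
        if amps is None:
            continue
        amps = np.broadcast_to(np.asarray(amps, dtype=float), (n_ch,))
        i0 = int(round(tr.onset * fs))
        seg = min(n - i0, int(round((tr.duration + 25.0) * fs)))
        if seg <= 0:
            continue
        resp = trial_response(
            fs, tr.duration, truth.hrf_peak_time, truth.hrf_undershoot_ratio, seg
        )
        hbo[i0 : i0 + seg] += resp[:, None] * amps[None, :]

    if schedule.paradigm == "fc":
        mixed = truth.fc_amplitude * _correlated_latents(
            rng, n, fs, truth.fc_band, truth.region_correlation
        )  # (n, 4)
        for k, region in enumerate(ROI_ORDER):
            hbo[:, layout.region_channels(region)] += mixed[:, k][:, None]

    lag = int(round(truth.hbr_lag * fs))
    hbr = -truth.hbr_ratio * np.roll(hbo, lag, axis=0)
    if lag > 0:
        hbr[:lag] = hbr[lag]
    return HbSubject(hbo, hbr, fs, schedule, layout, truth)


def inject_artifacts_and_noise(subject: HbSubject, truth: GroundTruth | None = None) -> HbSubject:
    """Add physiological noise and motion artifacts in the Hb domain.

    The cardiac oscillation is shared and amplitude-modulated; after the
    forward Beer-Lambert rendering it appears coherently on both
    wavelengths, which is what the scalp coupling index measures.
    Channels listed in ``bad_channels`` get no cardiac coupling (their
    optode-scalp contact is broken; the renderer replaces their optical
    signal with wavelength-independent noise).
    """
    truth = truth or subject.truth
    n, n_ch = subject.hbo.shape
    fs = subject.fs
    t = np.arange(n) / fs
    rng = np.random.default_rng(truth.seed + 104729)
    p = truth.noise_params
    hbo = subject.hbo.copy()
    hbr = subject.hbr.copy()

    bad = np.array(
        [cid in truth.bad_channels for cid in subject.layout.channel_id], dtype=bool
    )
    coupling = np.where(bad, 0.0, 1.0)

    if p.get("cardiac", 0) > 0:
        mod = 1.0 + 0.3 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
        card = p["cardiac"] * mod * np.sin(
            2 * np.pi * truth.cardiac_freq * t + rng.uniform(0, 2 * np.pi)
        )
        hbo += card[:, None] * coupling[None, :]
        hbr += 0.3 * card[:, None] * coupling[None, :]
    if p.get("respiratory", 0) > 0:
        resp = p["respiratory"] * np.sin(2 * np.pi * 0.7 * t + rng.uniform(0, 2 * np.pi))
        hbo += resp[:, None]
    if p.get("vasomotor", 0) > 0:
        vaso = p["vasomotor"] * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
        hbo += vaso[:, None]
    if p.get("drift", 0) > 0:
        for c in range(n_ch):
            hbo[:, c] += p["drift"] * _one_over_f(rng, n, fs)
    if p.get("white", 0) > 0:
        hbo += p["white"] * rng.standard_normal((n, n_ch))
        hbr += 0.5 * p["white"] * rng.standard_normal((n, n_ch))

    for time_s, kind, magnitude in truth.artifact_events:
        if not 0 <= time_s <= n / fs:
            raise ValueError(f"artifact event at {time_s} s outside span")
        i0 = int(round(time_s * fs))
        if kind == "spike":
            half = int(round(0.5 * fs))
            idx = np.arange(max(0, i0 - half), min(n, i0 + half + 1))
            bump = magnitude * np.exp(-0.5 * ((idx - i0) / (0.15 * fs)) ** 2)
            hbo[idx] += bump[:, None]
        elif kind == "shift":
            hbo[i0:] += magnitude
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")

    return HbSubject(hbo, hbr, fs, subject.schedule, subject.layout, truth)


def forward_mbll(
    subject: HbSubject,
    optics: OpticalConstants | None = None,
    *,
    i0: float = 1.0,
) -> RawRecording:
    """Render Hb series to raw two-wavelength intensities.

    intensity(lambda, t) = I0 * 10^(-dOD(lambda, t)) with dOD from the
    modified Beer-Lambert law. Channels flagged bad in the ground truth
    are replaced by wavelength-independent noise (no shared physiology),
    emulating a detached optode.
    """
    if i0 <= 0:
        raise ValueError("I0 must be positive")
    optics = optics or OpticalConstants(d=subject.layout.sd_separation / 10.0)
    od = hb_to_od(subject.hbo * 1.0, subject.hbr * 1.0, optics)  # (t, ch, 2)

    truth = subject.truth
    bad_idx = [
        i for i, cid in enumerate(subject.layout.channel_id) if cid in truth.bad_channels
    ]
    if bad_idx:
        rng = np.random.default_rng(truth.seed + 15485863)
        n = od.shape[0]
        od_scale = max(float(np.abs(od).mean()), 1e-4)
        for i in bad_idx:
            for w in range(2):
                od[:, i, w] = od_scale * (
                    rng.standard_normal(n) + 2.0 * _one_over_f(rng, n)
                )

    intensity = i0 * np.power(10.0, -od)
    events = [
        Event(tr.onset, f"{tr.condition}" + (f"/{tr.phase}" if tr.phase else ""))
        for tr in subject.schedule.trials
    ]
    return RawRecording(intensity, subject.fs, events, subject.layout)


@dataclass
class CohortConfig:
    """Between-subject distributions for a simulated cohort.

    Amplitude entries are (mean, sd) in uM applied on the listed 1-based
    channel ids; other channels get zero task response. Defaults plant
    the qualitative pattern the pipeline is designed to detect:
    habituation (Fam1 > Fam3) on left channels 4 and 7, nonvocal > vocal
    selectivity on the temporal channels, and stronger temporal than
    frontal inter-hemispheric slow-band coupling.
    """

    social_channels: tuple[int, ...] = (4, 5, 6, 7, 13, 14, 15, 16)
    n_amp: tuple[float, float] = (1.0, 0.3)
    v_amp: tuple[float, float] = (0.6, 0.3)
    hand_channels: tuple[int, ...] = (4, 7)
    fam1_amp: tuple[float, float] = (1.0, 0.3)
    habituation: tuple[float, float] = (0.7, 0.3)  # Fam1 - Fam3 difference
    novelty: tuple[float, float] = (0.0, 0.0)  # Nov - Fam3 difference
    region_correlation: np.ndarray | None = None
    fc_amplitude: float = 0.8
    noise_params: dict[str, float] | None = None
    n_bad_channels: int = 0
    artifact_rate: float = 0.0  # expected motion spikes per minute

    def correlation(self) -> np.ndarray:
        if self.region_correlation is not None:
            return np.asarray(self.region_correlation, dtype=float)
        return default_region_correlation()


def default_region_correlation() -> np.ndarray:
    """Planted 4x4 ROI correlation (LF, LT, RF, RT): temporal
    inter-hemispheric strongest, frontal weakest, between-region medium."""
    C = np.eye(4)
    pairs = {
        (0, 2): 0.05,  # LF-RF frontal IHC (weak)
        (1, 3): 0.75,  # LT-RT temporal IHC (strong)
        (0, 3): 0.45,  # LF-RT between-region IHC
        (1, 2): 0.45,  # LT-RF between-region IHC
        (0, 1): 0.30,  # LF-LT intra left
        (2, 3): 0.30,  # RF-RT intra right
    }
    for (i, j), r in pairs.items():
        C[i, j] = C[j, i] = r
    if np.linalg.eigvalsh(C).min() < 0:  # pragma: no cover - defaults are PSD
        raise ValueError("default correlation not PSD")
    return C


def _subject_truth(config: CohortConfig, layout: ProbeLayout, rng) -> GroundTruth:
    n_ch = layout.n_channels
    ids = layout.channel_id

    def on_channels(chans, value):
        amps = np.zeros(n_ch)
        amps[np.isin(ids, chans)] = value
        return amps

    n_amp = rng.normal(*config.n_amp)
    v_amp = rng.normal(*config.v_amp)
    fam1 = rng.normal(*config.fam1_amp)
    hab = rng.normal(*config.habituation)
    nov = rng.normal(*config.novelty) if config.novelty[1] or config.novelty[0] else 0.0
    fam3 = fam1 - hab
    amplitude_map = {
        "N": on_channels(config.social_channels, n_amp),
        "V": on_channels(config.social_channels, v_amp),
        "Fam1": on_channels(config.hand_channels, fam1),
        "Fam2": on_channels(config.hand_channels, 0.5 * (fam1 + fam3)),
        "Fam3": on_channels(config.hand_channels, fam3),
        "Nov": on_channels(config.hand_channels, fam3 + nov),
        "ReFam": on_channels(config.hand_channels, fam3),
    }
    bad = frozenset(
        int(c) for c in rng.choice(ids, size=config.n_bad_channels, replace=False)
    )
    return GroundTruth(
        amplitude_map=amplitude_map,
        region_correlation=config.correlation(),
        fc_amplitude=config.fc_amplitude,
        bad_channels=bad,
        noise_params=dict(config.noise_params or DEFAULT_NOISE),
        cardiac_freq=float(rng.uniform(1.8, 3.0)),
        seed=int(rng.integers(2**31)),
    )


@dataclass
class SimulatedSubject:
    subject_id: str
    truth: GroundTruth
    recordings: dict[str, RawRecording]  # paradigm -> raw recording


def simulate_cohort(
    n_subjects: int,
    config: CohortConfig | None = None,
    master_seed: int = 0,
    *,
    paradigms: tuple[str, ...] = ("social", "hand", "fc"),
    fs: float = 10.0,
    layout: ProbeLayout | None = None,
) -> list[SimulatedSubject]:
    """Simulate a cohort; paradigms generated in the session order
    social -> hand -> fc. Deterministic given ``master_seed``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or CohortConfig()
    layout = layout or build_probe_layout("bright18")
    master = np.random.default_rng(master_seed)
    subjects = []
    for s in range(n_subjects):
        rng = np.random.default_rng(int(master.integers(2**31)))
        truth = _subject_truth(config, layout, rng)
        recs = {}
        for paradigm in paradigms:
            sched = build_schedule(paradigm, seed=int(rng.integers(2**31)))
            if config.artifact_rate > 0:
                n_art = rng.poisson(config.artifact_rate * sched.total_duration / 60.0)
                events = [
                    (float(rng.uniform(5, sched.total_duration + 10)),
                     "spike" if rng.random() < 0.7 else "shift",
                     float(rng.normal(0, 2.0)))
                    for _ in range(n_art)
                ]
            else:
                events = []
            sub_truth = replace(truth, artifact_events=events,
                                seed=int(rng.integers(2**31)))
            clean = simulate_subject(layout, sched, sub_truth, fs=fs)
            noisy = inject_artifacts_and_noise(clean)
            recs[paradigm] = forward_mbll(noisy)
        subjects.append(SimulatedSubject(f"sub-{s + 1:03d}", truth, recs))
    return subjects
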