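"""ROI functional connectivity for the resting (sleeping) paradigm.

Chain: optical density -> zero-phase bandpass 0.009-3 Hz -> global
signal regression (the across-channel mean regressed from every
channel) -> second bandpass 0.009-0.08 Hz -> motion censoring on the
global variance of temporal derivatives (GVTD, 5 robust SD above the
median, plus a 5 s guard either side) -> Beer-Lambert inversion ->
unweighted ROI averages (LF, LT, RF, RT) -> 4x4 Pearson correlation on
the censored-valid samples -> Fisher z. Subjects need at least 120 s of
valid data. Inter-hemispheric pairs: LF-RF, LT-RT, LF-RT, LT-RF;
intra-hemispheric: LF-LT, RF-RT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .layout import ProbeLayout, ROI_ORDER
from .optics import OpticalConstants, od_to_hb_arrays
from .preprocess import intensity_to_od
from .quality import ChannelQualityReport
from .recording import RawRecording

ROI_SHORT = ("LF", "LT", "RF", "RT")
INTER_PAIRS = (("LF", "RF"), ("LT", "RT"), ("LF", "RT"), ("LT", "RF"))
INTRA_PAIRS = (("LF", "LT"), ("RF", "RT"))
ALL_PAIRS = INTER_PAIRS + INTRA_PAIRS


@dataclass(frozen=True)
class FcParams:
    wide_band: tuple[float, float] = (0.009, 3.0)  # Hz
    narrow_band: tuple[float, float] = (0.009, 0.08)  # Hz
    gvtd_sd_multiplier: float = 5.0
    guard: float = 5.0  # s excluded either side of an artifact
    min_valid: float = 120.0  # s
    r_clip: float = 0.999999
    optics: OpticalConstants = field(default_factory=OpticalConstants)

    def validate(self, fs: float) -> None:
        for lo, hi in (self.wide_band, self.narrow_band):
            if not 0 < lo < hi:
                raise ValueError("band edges must be ordered and positive")
            if lo >= fs / 2:
                raise ValueError("band lies above Nyquist")
        if self.guard < 0 or self.min_valid <= 0:
            raise ValueError("guard must be >= 0 and min_valid > 0")


@dataclass
class ConnectivityResult:
    r: dict[str, np.ndarray]  # chromophore -> 4x4 Pearson matrix
    z: dict[str, np.ndarray]  # chromophore -> 4x4 Fisher-z matrix
    pair_values: pd.DataFrame  # long table: chromophore, pair, kind, r, z
    inter_mean: dict[str, float]  # mean of the 4 inter-hemispheric z
    intra_mean: dict[str, float]  # mean of the 2 intra-hemispheric z
    valid_seconds: float


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2
    if hi >= nyq:  # stated 3 Hz upper edge sits at fs=10 Nyquist margin
        hi = 0.99 * nyq
    sos = sps.butter(3, (lo, hi), btype="bandpass", fs=fs, output="sos")
    # the 0.009 Hz high-pass edge has a ~110 s time constant; extend the
    # filtfilt reflection padding accordingly (capped by series length)
    padlen = min(x.shape[0] - 1, int(3 * fs / lo))
    return sps.sosfiltfilt(sos, x - x.mean(axis=0, keepdims=True), axis=0,
                           padlen=padlen)


def fc_filter_chain(od: np.ndarray, fs: float, params: FcParams | None = None) -> np.ndarray:
    """Wide bandpass -> global signal regression -> narrow bandpass.

    Operates on (time, channel, ...) arrays; GSR regresses the
    across-channel mean from each channel by least squares.
    """
    params = params or FcParams()
    params.validate(fs)
    if od.ndim >= 2 and od.shape[1] < 2:
        raise ValueError("global signal regression needs >= 2 channels")
    wide = _bandpass(od, fs, params.wide_band)
    flat = wide.reshape(wide.shape[0], -1) if wide.ndim > 2 else wide
    out = np.empty_like(wide)
    # regress the global mean out of every channel, per trailing index
    if wide.ndim == 3:
        for w in range(wide.shape[2]):
            out[:, :, w] = _gsr(wide[:, :, w])
    else:
        out = _gsr(wide)
    return _bandpass(out, fs, params.narrow_band)


def _gsr(x: np.ndarray) -> np.ndarray:
    g = x.mean(axis=1)
    gc = g - g.mean()
    denom = float(gc @ gc)
    if denom == 0:
        return x - x.mean(axis=0, keepdims=True)
    xc = x - x.mean(axis=0, keepdims=True)
    beta = (gc @ xc) / denom
    return xc - np.outer(gc, beta)


def gvtd(series: np.ndarray) -> np.ndarray:
    """Global variance of temporal derivatives: RMS across channels of
    the first difference; length matches the series (first sample 0)."""
    flat = series.reshape(series.shape[0], -1)
    d = np.diff(flat, axis=0)
    g = np.sqrt((d**2).mean(axis=1))
    return np.concatenate([[0.0], g])


def gvtd_censor(
    series: np.ndarray, fs: float, params: FcParams | None = None
) -> tuple[np.ndarray, float]:
    """Valid-sample mask from the GVTD motion index.

    Threshold = median(GVTD) + multiplier * robust SD (1.4826 MAD);
    samples above it, plus ``guard`` seconds on both sides, are invalid.
    Returns (mask, valid_seconds).
    """
    params = params or FcParams()
    if series.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    g = gvtd(series)
    med = np.median(g)
    mad_sd = 1.4826 * np.median(np.abs(g - med))
    thresh = med + params.gvtd_sd_multiplier * mad_sd
    bad = g > thresh
    guard_n = int(round(params.guard * fs))
    if bad.any() and guard_n > 0:
        idx = np.flatnonzero(bad)
        mask_bad = np.zeros_like(bad)
        for i in idx:
            mask_bad[max(0, i - guard_n) : i + guard_n + 1] = True
        bad = mask_bad
    mask = ~bad
    return mask, float(mask.sum() / fs)


def check_min_valid(mask: np.ndarray, fs: float, params: FcParams | None = None) -> bool:
    """Included iff at least ``min_valid`` seconds survive censoring."""
    params = params or FcParams()
    return float(mask.sum() / fs) >= params.min_valid


def roi_average(
    hb: np.ndarray, layout: ProbeLayout, qc: ChannelQualityReport | None = None
) -> np.ndarray:
    """Unweighted mean over unflagged channels per ROI -> (time, 4)
    in the fixed order LF, LT, RF, RT."""
    good = qc.good_channel_mask() if qc is not None else np.ones(hb.shape[1], bool)
    out = np.empty((hb.shape[0], 4))
    for k, region in enumerate(ROI_ORDER):
        members = layout.region_channels(region)
        members = members[good[members]]
        if members.size == 0:
            raise ValueError(f"ROI {region} has no valid channels; subject excluded")
        out[:, k] = hb[:, members].mean(axis=1)
    return out


def connectivity_matrix(
    roi_series: dict[str, np.ndarray],
    mask: np.ndarray,
    fs: float,
    params: FcParams | None = None,
) -> ConnectivityResult:
    """4x4 Pearson/Fisher-z matrices on censored-valid samples.

    ``roi_series`` maps chromophore ("HbO"/"HbR") to a (time, 4) array.
    Censored samples are dropped and the valid segments concatenated.
    """
    params = params or FcParams()
    valid_seconds = float(mask.sum() / fs)
    if valid_seconds < params.min_valid:
        raise ValueError(
            f"only {valid_seconds:.1f} s valid, below the {params.min_valid:.0f} s minimum"
        )
    r_all, z_all, inter_mean, intra_mean = {}, {}, {}, {}
    rows = []
    for chrom, series in roi_series.items():
        x = series[mask]
        if np.any(x.std(axis=0) == 0):
            bad = [ROI_SHORT[i] for i in np.flatnonzero(x.std(axis=0) == 0)]
            raise ValueError(f"constant ROI series {bad}; correlation undefined")
        r = np.corrcoef(x.T)
        z = np.arctanh(np.clip(r, -params.r_clip, params.r_clip))
        r_all[chrom], z_all[chrom] = r, z
        pair_z = {}
        for a, b in ALL_PAIRS:
            i, j = ROI_SHORT.index(a), ROI_SHORT.index(b)
            kind = "inter" if (a, b) in INTER_PAIRS else "intra"
            rows.append((chrom, f"{a}-{b}", kind, float(r[i, j]), float(z[i, j])))
            pair_z[(a, b)] = float(z[i, j])
        inter_mean[chrom] = float(np.mean([pair_z[p] for p in INTER_PAIRS]))
        intra_mean[chrom] = float(np.mean([pair_z[p] for p in INTRA_PAIRS]))
    table = pd.DataFrame(rows, columns=["chromophore", "pair", "kind", "r", "z"])
    return ConnectivityResult(r_all, z_all, table, inter_mean, intra_mean, valid_seconds)


def analyze_fc_recording(
    rec: RawRecording,
    qc: ChannelQualityReport | None = None,
    params: FcParams | None = None,
) -> ConnectivityResult:
    """Full FC pipeline for one subject's resting recording."""
    params = params or FcParams()
    od = intensity_to_od(rec)
    narrow = fc_filter_chain(od, rec.fs, params)
    mask, _ = gvtd_censor(narrow, rec.fs, params)
    hbo, hbr = od_to_hb_arrays(narrow, params.optics)
    roi = {
        "HbO": roi_average(hbo, rec.layout, qc),
        "HbR": roi_average(hbr, rec.layout, qc),
    }
    return connectivity_matrix(roi, mask, rec.fs, params)


def summarize_connectivity(
    results: list[ConnectivityResult], chromophore: str = "HbO"
) -> dict:
    """Cohort summary: per-subject table, paired inter-vs-intra t-test,
    and a GG-corrected repeated-measures ANOVA over the four
    inter-hemispheric pairs with FDR post-hocs against the temporal pair.
    """
    from .stats import adjust_pvalues, paired_ttest, rm_anova_gg

    if len(results) < 3:
        raise ValueError("need >= 3 subjects to summarise connectivity")
    inter = np.array([r.inter_mean[chromophore] for r in results])
    intra = np.array([r.intra_mean[chromophore] for r in results])
    t, df, p = paired_ttest(inter, intra)

    pair_names = [f"{a}-{b}" for a, b in INTER_PAIRS]
    def pair_z(r, name):
        pv = r.pair_values
        sel = (pv["chromophore"] == chromophore) & (pv["pair"] == name)
        return float(pv.loc[sel, "z"].iloc[0])

    pair_matrix = np.array(
        [[pair_z(r, name) for name in pair_names] for r in results]
    )
    anova = rm_anova_gg(pair_matrix)
    temporal = pair_matrix[:, pair_names.index("LT-RT")]
    post_p, post_t = [], []
    others = [n for n in pair_names if n != "LT-RT"]
    for name in others:
        tt, _, pp = paired_ttest(temporal, pair_matrix[:, pair_names.index(name)])
        post_t.append(tt)
        post_p.append(pp)
    post_adj = adjust_pvalues(post_p, "bh")
    return {
        "n": len(results),
        "inter_mean": float(inter.mean()),
        "intra_mean": float(intra.mean()),
        "paired_t": {"t": t, "df": df, "p": p},
        "anova": anova,
        "posthoc": [
            {"pair": name, "t": tt, "p_raw": pp, "p_fdr": pa}
            for name, tt, pp, pa in zip(others, post_t, post_p, post_adj)
        ],
        "pair_names": pair_names,
        "pair_means_z": pair_matrix.mean(axis=0).tolist(),
    }
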