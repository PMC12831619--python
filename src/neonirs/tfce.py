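"""Channel-by-time threshold-free cluster enhancement (TFCE) statistics.

For each contrast a subject-level difference map (channel x time) feeds
a one-sample t-map across subjects. TFCE integrates, over an evenly
stepped threshold ladder, each supra-threshold connected component's
extent^E times height^H (defaults E = 1, H = 2), where connectivity
joins channels within the spatial adjacency radius (20 mm) at the same
time sample and the same channel at adjacent time samples. Significance
comes from a sign-flip permutation null with element-wise p-values,
Benjamini-Hochberg FDR at q = 0.025 per direction, and a robustness
rule deleting significant runs shorter than 1 s. Condition-difference
significance is gated on the favoured condition's versus-baseline
significance at the same channel. Cluster time windows are the medians
of per-channel onsets/offsets, and a 4 s extraction window is centred on
the window midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .preprocess import EpochSet

T_SENTINEL = 1e6  # cap for zero-variance t statistics

#: contrast label -> (favoured label, other label or None for baseline)
CONTRASTS = {
    "N_vs_base": ("N", None),
    "V_vs_base": ("V", None),
    "N_vs_V": ("N", "V"),
    "V_vs_N": ("V", "N"),
    "Fam1_vs_base": ("Fam1", None),
    "Fam3_vs_base": ("Fam3", None),
    "Nov_vs_base": ("Nov", None),
    "Fam1_vs_Fam3": ("Fam1", "Fam3"),
    "Nov_vs_Fam3": ("Nov", "Fam3"),
}

#: condition-difference contrast -> prerequisite versus-baseline contrast
GATING_RULES = {
    "N_vs_V": "N_vs_base",
    "V_vs_N": "V_vs_base",
    "Fam1_vs_Fam3": "Fam1_vs_base",
    "Nov_vs_Fam3": "Nov_vs_base",
}


@dataclass(frozen=True)
class TfceParams:
    H: float = 2.0
    E: float = 1.0
    dh: float = 0.01  # reference ladder step (fraction of map maximum);
    # the enhancement itself integrates the ladder's limit exactly
    adjacency_radius: float = 20.0  # mm
    n_permutations: int = 1000
    alpha: float = 0.025  # per-direction level; also the BH q
    min_duration: float = 1.0  # s robustness rule
    extract_window: float = 4.0  # s
    min_subjects: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.H < 0 or self.E < 0 or self.dh <= 0:
            raise ValueError("H, E must be >= 0 and dh > 0")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if not 0 < self.alpha < 0.5:
            raise ValueError("alpha must be in (0, 0.5)")

    @property
    def fdr_q(self) -> float:
        return self.alpha


@dataclass
class StatMap:
    values: np.ndarray  # (channel, time) t statistics
    df: int
    contrast: str
    direction: str = "greater"
    chromophore: str = "HbO"
    element_valid: np.ndarray | None = None  # (channel, time) bool


@dataclass
class Cluster:
    channels: np.ndarray  # 0-based channel indices
    time_slice: tuple[int, int]  # [first, last] significant sample
    onset_median: float  # s
    offset_median: float  # s


@dataclass
class TfceResult:
    tmap: StatMap
    tfce: np.ndarray
    p: np.ndarray
    sig_mask: np.ndarray
    clusters: list[Cluster]
    params: TfceParams
    times: np.ndarray | None = None  # s, per map column


# ---------------------------------------------------------------------------
# TFCE enhancement (incremental union-find over descending thresholds)


@njit(cache=True)
def _findo(parent, off, i):
    """Find root with path compression, keeping per-node potential
    offsets consistent (off[i] = potential delta of i w.r.t. parent)."""
    root = i
    s = 0.0
    while parent[root] != root:
        s += off[root]
        root = parent[root]
    cur = i
    acc = s
    while parent[cur] != root:
        nxt = parent[cur]
        old = off[cur]
        off[cur] = acc
        parent[cur] = root
        acc -= old
        cur = nxt
    return root


@njit(cache=True)
def _tfce_exact(values, order, indptr, indices, E, Hp1):
    """Exact TFCE integral via incremental union-find.

    Nodes activate in descending value order; between merge events a
    component of size s accrues s**E * d(h**Hp1 / Hp1) to all members,
    tracked lazily as a per-root potential with offset bookkeeping.
    """
    n = values.size
    parent = np.full(n, -1, np.int64)
    size = np.zeros(n, np.int64)
    pot = np.zeros(n)
    off = np.zeros(n)
    last_g = np.zeros(n)
    tfce = np.zeros(n)
    for pos in range(n):
        node = order[pos]
        v = values[node]
        if v <= 0.0:
            break
        g = v**Hp1 / Hp1
        parent[node] = node
        size[node] = 1
        pot[node] = 0.0
        off[node] = 0.0
        last_g[node] = g
        for e in range(indptr[node], indptr[node + 1]):
            nb = indices[e]
            if parent[nb] != -1:
                ra = _findo(parent, off, node)
                rb = _findo(parent, off, nb)
                if ra != rb:
                    pot[ra] += (size[ra] ** E) * (last_g[ra] - g)
                    last_g[ra] = g
                    pot[rb] += (size[rb] ** E) * (last_g[rb] - g)
                    last_g[rb] = g
                    if size[ra] < size[rb]:
                        ra, rb = rb, ra
                    off[rb] = pot[rb] - pot[ra]
                    parent[rb] = ra
                    size[ra] += size[rb]
    for i in range(n):
        if parent[i] == i:
            pot[i] += (size[i] ** E) * last_g[i]
            last_g[i] = 0.0
    for i in range(n):
        if parent[i] != -1:
            root = _findo(parent, off, i)
            tfce[i] = pot[root] + (off[i] if i != root else 0.0)
    return tfce


def _grid_graph(adjacency: np.ndarray, n_time: int) -> tuple[np.ndarray, np.ndarray]:
    """CSR neighbour lists for the channel-time lattice.

    Node c*T + t connects to spatially adjacent channels at the same t
    and to the same channel at t +- 1.
    """
    n_ch = adjacency.shape[0]
    pairs_c = np.argwhere(adjacency)
    rows, cols = [], []
    t = np.arange(n_time)
    for i, j in pairs_c:  # directed both ways already (argwhere of symmetric)
        rows.append(i * n_time + t)
        cols.append(j * n_time + t)
    c = np.arange(n_ch)
    rows.append((c[:, None] * n_time + t[:-1][None, :]).ravel())
    cols.append((c[:, None] * n_time + t[1:][None, :]).ravel())
    rows.append((c[:, None] * n_time + t[1:][None, :]).ravel())
    cols.append((c[:, None] * n_time + t[:-1][None, :]).ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    order = np.argsort(rows, kind="stable")
    rows, cols = rows[order], cols[order]
    indptr = np.zeros(n_ch * n_time + 1, dtype=np.int64)
    np.add.at(indptr, rows + 1, 1)
    indptr = np.cumsum(indptr)
    return indptr, cols.astype(np.int64)


def tfce_enhance(
    values: np.ndarray,
    adjacency: np.ndarray,
    params: TfceParams | None = None,
    *,
    graph: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Enhance a (channel, time) statistic map; only values > 0 contribute.

    The supra-threshold component structure is piecewise constant in the
    threshold, so the enhancement sum over an evenly stepped ladder has
    a closed-form limit; it is evaluated exactly between component-merge
    events (equivalently, the ladder with the step taken to zero).
    """
    params = params or TfceParams()
    if values.size == 0:
        raise ValueError("empty statistic map")
    v = np.ascontiguousarray(values, dtype=np.float64)
    vmax = v.max()
    if not np.isfinite(vmax) or vmax <= 0:
        return np.zeros_like(v)
    if graph is None:
        graph = _grid_graph(adjacency, v.shape[1])
    indptr, indices = graph
    flat = v.ravel()
    order = np.argsort(-flat, kind="stable").astype(np.int64)
    out = _tfce_exact(flat, order, indptr, indices, params.E, params.H + 1.0)
    return out.reshape(v.shape)


# ---------------------------------------------------------------------------
# Subject-level maps and t statistics


def subject_difference_maps(
    epoch_sets: list[EpochSet], contrast: str, chromophore: str = "HbO"
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-subject (channel x time) difference maps for a contrast.

    Versus-baseline contrasts use the subject's trial-averaged
    (baseline-corrected) response; condition-condition contrasts the
    difference of condition means. Returns (maps, times); masked
    channels are NaN.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    fav, other = CONTRASTS[contrast]
    maps = []
    times = epoch_sets[0].times
    for es in epoch_sets:
        chrom = "hbo" if chromophore.lower() == "hbo" else "hbr"
        try:
            m = es.condition_mean(fav, chrom)
            if other is not None:
                m = m - es.condition_mean(other, chrom)
        except ValueError:
            continue  # subject has no valid trials for a needed label
        maps.append(m)
    if len(maps) < 2:
        raise ValueError(f"need >= 2 subjects with valid data for {contrast!r}")
    return np.stack(maps), times


def _t_from_sums(sum1, sum2, n):
    """One-sample t from signed sums; degenerate variance capped."""
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sum1 / n
        var = (sum2 - n * mean**2) / (n - 1)
        var = np.maximum(var, 0.0)
        t = mean / np.sqrt(var / n)
    t = np.where(var <= 0, np.where(mean == 0, 0.0, np.sign(mean) * T_SENTINEL), t)
    t = np.clip(t, -T_SENTINEL, T_SENTINEL)
    return np.where(n >= 2, t, 0.0)


def pointwise_tmap(
    epoch_sets: list[EpochSet],
    contrast: str,
    chromophore: str = "HbO",
    direction: str = "greater",
    min_subjects: int = 2,
) -> StatMap:
    """Across-subject one-sample t-map for a contrast."""
    maps, _ = subject_difference_maps(epoch_sets, contrast, chromophore)
    return _tmap_from_maps(maps, contrast, chromophore, direction, min_subjects)


def _tmap_from_maps(maps, contrast, chromophore, direction, min_subjects):
    w = np.isfinite(maps)
    x = np.where(w, maps, 0.0)
    n = w.sum(axis=0).astype(float)
    t = _t_from_sums(x.sum(axis=0), (x**2).sum(axis=0), np.maximum(n, 2))
    valid = n >= max(min_subjects, 2)
    t = np.where(valid, t, 0.0)
    df = int(np.max(n)) - 1 if n.size else 0
    return StatMap(t, df, contrast, direction, chromophore, element_valid=valid)


# ---------------------------------------------------------------------------
# Permutation p-values


def permutation_pvalues(
    maps: np.ndarray,
    adjacency: np.ndarray,
    params: TfceParams | None = None,
    *,
    contrast: str = "contrast",
    chromophore: str = "HbO",
    direction: str = "greater",
) -> tuple[np.ndarray, np.ndarray, StatMap]:
    """Sign-flip permutation TFCE p-values for subject difference maps.

    Returns (p, observed TFCE, observed StatMap). p at each element is
    (1 + #{null TFCE >= observed}) / (1 + n_permutations).
    """
    params = params or TfceParams()
    n_subj = maps.shape[0]
    if n_subj < 6:
        import warnings

        warnings.warn(f"only {n_subj} subjects; permutation null is coarse")
    sign = 1.0 if direction == "greater" else -1.0
    w = np.isfinite(maps)
    x = np.where(w, sign * maps, 0.0)
    n = np.maximum(w.sum(axis=0).astype(float), 2)
    sum2 = (x**2).sum(axis=0)  # invariant under sign flips

    stat = _tmap_from_maps(sign * maps, contrast, chromophore, direction,
                           params.min_subjects)
    stat.values *= sign  # report t in the original orientation
    valid = stat.element_valid
    graph = _grid_graph(adjacency, maps.shape[2])

    def enhance(t):
        t = np.where(valid, t, 0.0)
        return tfce_enhance(t, adjacency, params, graph=graph)

    t_obs = _t_from_sums(x.sum(axis=0), sum2, n)
    obs_tfce = enhance(t_obs)

    rng = np.random.default_rng(params.rng_seed)
    flat_x = x.reshape(n_subj, -1)
    count = np.zeros(obs_tfce.shape)
    for _ in range(params.n_permutations):
        signs = rng.choice(np.array([-1.0, 1.0]), size=n_subj)
        sum1 = (signs @ flat_x).reshape(x.shape[1:])
        t_perm = _t_from_sums(sum1, sum2, n)
        count += enhance(t_perm) >= obs_tfce
    p = (1.0 + count) / (1.0 + params.n_permutations)
    p = np.where(valid, p, 1.0)
    return p, obs_tfce, stat


# ---------------------------------------------------------------------------
# FDR, pruning, clusters


def bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask over a flat array."""
    p = np.asarray(p, dtype=float)
    m = p.size
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = q * np.arange(1, m + 1) / m
    below = np.flatnonzero(ranked <= crit)
    mask = np.zeros(m, dtype=bool)
    if below.size:
        mask[order[: below[-1] + 1]] = True
    return mask


def _prune_short_runs(mask: np.ndarray, min_samples: int) -> np.ndarray:
    out = mask.copy()
    for c in range(mask.shape[0]):
        row = out[c]
        i = 0
        n = row.size
        while i < n:
            if row[i]:
                j = i
                while j < n and row[j]:
                    j += 1
                if j - i < min_samples:
                    row[i:j] = False
                i = j
            else:
                i += 1
    return out


def _connected_clusters(mask: np.ndarray, adjacency: np.ndarray) -> list[np.ndarray]:
    """Connected components of a significance mask under the TFCE
    connectivity; returns flat element-index arrays."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n_ch, n_t = mask.shape
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        return []
    pos = -np.ones(n_ch * n_t, dtype=np.int64)
    pos[idx] = np.arange(idx.size)
    indptr, indices = _grid_graph(adjacency, n_t)
    rows, cols = [], []
    for k, node in enumerate(idx):
        for e in range(indptr[node], indptr[node + 1]):
            nb = pos[indices[e]]
            if nb >= 0:
                rows.append(k)
                cols.append(nb)
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(idx.size, idx.size)
    )
    n_comp, labels = connected_components(graph, directed=False)
    return [idx[labels == k] for k in range(n_comp)]


def fdr_mask_and_prune(
    p: np.ndarray,
    params: TfceParams | None = None,
    fs: float = 10.0,
    adjacency: np.ndarray | None = None,
    element_valid: np.ndarray | None = None,
) -> tuple[np.ndarray, list[Cluster]]:
    """BH-FDR at q, then delete per-channel runs shorter than 1 s;
    clusters are connected components of the surviving mask."""
    params = params or TfceParams()
    if element_valid is None:
        element_valid = np.ones_like(p, dtype=bool)
    mask = np.zeros_like(p, dtype=bool)
    flat_valid = element_valid.ravel()
    rej = bh_reject(p.ravel()[flat_valid], params.fdr_q)
    mask.ravel()[np.flatnonzero(flat_valid)[rej]] = True
    min_samples = max(1, int(round(params.min_duration * fs)))
    mask = _prune_short_runs(mask, min_samples)

    clusters: list[Cluster] = []
    if adjacency is not None and mask.any():
        n_t = mask.shape[1]
        for comp in _connected_clusters(mask, adjacency):
            ch = comp // n_t
            chans = np.unique(ch)
            onsets, offsets = [], []
            for c in chans:
                ts = comp[ch == c] % n_t
                onsets.append(ts.min())
                offsets.append(ts.max())
            clusters.append(
                Cluster(
                    channels=chans,
                    time_slice=(int(min(onsets)), int(max(offsets))),
                    onset_median=float(np.median(onsets) / fs),
                    offset_median=float(np.median(offsets) / fs),
                )
            )
    return mask, clusters


# ---------------------------------------------------------------------------
# High-level contrast analysis, gating and window extraction


def run_contrast(
    epoch_sets: list[EpochSet],
    contrast: str,
    adjacency: np.ndarray,
    params: TfceParams | None = None,
    chromophore: str = "HbO",
    direction: str = "greater",
) -> TfceResult:
    """Full TFCE analysis of one contrast on a subject collection."""
    params = params or TfceParams()
    maps, times = subject_difference_maps(epoch_sets, contrast, chromophore)
    p, tfce, stat = permutation_pvalues(
        maps, adjacency, params, contrast=contrast, chromophore=chromophore,
        direction=direction,
    )
    fs = epoch_sets[0].fs
    mask, clusters = fdr_mask_and_prune(
        p, params, fs, adjacency, element_valid=stat.element_valid
    )
    # report onsets/offsets relative to stimulus onset
    for cl in clusters:
        cl.onset_median += float(times[0])
        cl.offset_median += float(times[0])
    return TfceResult(stat, tfce, p, mask, clusters, params, times=times)


def gate_contrasts(results: dict[str, TfceResult]) -> dict[str, TfceResult]:
    """Apply the condition-versus-baseline gating rules.

    A channel's condition-difference significance survives only if the
    favoured condition's versus-baseline mask is significant at that
    channel (any time sample). Versus-baseline results pass through.
    """
    gated: dict[str, TfceResult] = {}
    for label, res in results.items():
        req = GATING_RULES.get(label)
        if req is None:
            gated[label] = res
            continue
        if req not in results:
            raise ValueError(f"contrast {label!r} requires {req!r} to be computed")
        base_channels = results[req].sig_mask.any(axis=1)
        mask = res.sig_mask & base_channels[:, None]
        clusters = [c for c in res.clusters if np.all(base_channels[c.channels])]
        gated[label] = TfceResult(
            res.tmap, res.tfce, res.p, mask, clusters, res.params, res.times
        )
    return gated


def median_window(cluster: Cluster, extract_window: float = 4.0) -> tuple[float, float]:
    """Centre a 4 s extraction window at the midpoint of the cluster's
    median [onset, offset] interval."""
    centre = 0.5 * (cluster.onset_median + cluster.offset_median)
    return centre - extract_window / 2.0, centre + extract_window / 2.0


def extract_windows(
    epoch_sets: list[EpochSet],
    roi: np.ndarray,
    window: tuple[float, float],
    contrast: str,
    chromophore: str = "HbO",
    subject_ids: list[str] | None = None,
):
    """Per-subject scalar means over roi channels x time window (uM).

    ``window`` is in seconds relative to stimulus onset and may come
    from :func:`median_window` or be supplied externally. For
    condition-difference contrasts the value is the difference of the
    condition means over the same window.
    """
    import pandas as pd

    roi = np.asarray(roi)
    if roi.size == 0:
        raise ValueError("empty ROI")
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    fav, other = CONTRASTS[contrast]
    w0, w1 = window
    rows = []
    for s, es in enumerate(epoch_sets):
        tmask = (es.times >= w0) & (es.times <= w1)
        if not tmask.any():
            raise ValueError("extraction window falls outside the epoch")
        chrom = "hbo" if chromophore.lower() == "hbo" else "hbr"
        try:
            m = es.condition_mean(fav, chrom)
            if other is not None:
                m = m - es.condition_mean(other, chrom)
        except ValueError:
            continue
        sub = m[np.ix_(roi, np.flatnonzero(tmask))]
        value = float(np.nanmean(sub)) if np.isfinite(sub).any() else np.nan
        sid = subject_ids[s] if subject_ids else f"sub-{s + 1:03d}"
        rows.append((sid, contrast, chromophore, w0, w1, value))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "contrast", "chromophore", "window_start",
                 "window_end", "value"],
    )
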