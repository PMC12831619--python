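"""Probe geometry for the 18-channel infant array.

Two arrays of nine channels each cover the left and right hemispheres,
with source-detector pairs at a 2 cm separation. Each hemisphere is
partitioned into a frontal and a temporal region of interest, giving the
four ROIs (left frontal, left temporal, right frontal, right temporal)
used for spatial clustering and functional connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGIONS = ("left_frontal", "left_temporal", "right_frontal", "right_temporal")
ROI_ORDER = REGIONS  # fixed LF, LT, RF, RT ordering everywhere

# Channel -> region assignment for the "bright18" preset. Channels 1-9 are
# left hemisphere, 10-18 right; the right array mirrors the left via +9.
_BRIGHT18_REGIONS = {
    "left_frontal": (1, 2, 3, 8),
    "left_temporal": (4, 5, 6, 7, 9),
    "right_frontal": (10, 11, 12, 17),
    "right_temporal": (13, 14, 15, 16, 18),
}

# In-plane (anterior, superior) offsets in mm shared by both hemispheres;
# lateral coordinate is +-70 mm. Within each region nearest neighbours sit
# <= 20 mm apart so the 20 mm adjacency radius connects them; channels 1
# and 4 form the single frontal-temporal bridge that keeps each
# hemisphere's adjacency graph connected (matching the frontal-temporal
# clusters the array is designed to resolve).
_BRIGHT18_YZ = {
    1: (30.0, 10.0),
    2: (45.0, 18.0),
    3: (60.0, 10.0),
    8: (45.0, 0.0),
    4: (15.0, 0.0),
    5: (0.0, 8.0),
    6: (-15.0, 0.0),
    7: (15.0, -16.0),
    9: (-15.0, -16.0),
}


@dataclass(frozen=True)
class ProbeLayout:
    """Channel geometry, hemisphere/region labels and SD separation.

    Attributes
    ----------
    channel_id : (n,) int array, 1-based channel numbers.
    position : (n, 3) float array, scalp-surface coordinates in mm.
    hemisphere : (n,) array of {"left", "right"}.
    region : (n,) array of region labels (one of ``REGIONS``).
    sd_separation : source-detector distance in mm (default 20).
    """

    channel_id: np.ndarray
    position: np.ndarray
    hemisphere: np.ndarray
    region: np.ndarray
    sd_separation: float = 20.0

    def __post_init__(self) -> None:
        n = len(self.channel_id)
        if len(set(self.channel_id.tolist())) != n:
            raise ValueError("duplicate channel ids")
        if self.position.shape != (n, 3):
            raise ValueError("position must be (n, 3)")
        unknown = set(self.region.tolist()) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region label(s): {sorted(unknown)}")
        left = int(np.sum(self.hemisphere == "left"))
        right = int(np.sum(self.hemisphere == "right"))
        if n == 18 and (left != 9 or right != 9):
            raise ValueError("expected 9 channels per hemisphere")
        d = self.pairwise_distances()
        if np.any(d[np.triu_indices(n, 1)] <= 0):
            raise ValueError("coincident channel positions")
        if self.sd_separation <= 0:
            raise ValueError("sd_separation must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_id)

    def pairwise_distances(self) -> np.ndarray:
        diff = self.position[:, None, :] - self.position[None, :, :]
        return np.sqrt((diff**2).sum(-1))

    def region_channels(self, region: str) -> np.ndarray:
        """0-based indices of the channels belonging to ``region``."""
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return np.flatnonzero(self.region == region)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel_id": self.channel_id,
                "x": self.position[:, 0],
                "y": self.position[:, 1],
                "z": self.position[:, 2],
                "hemisphere": self.hemisphere,
                "region": self.region,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_probe_layout(spec: str | pd.DataFrame = "bright18") -> ProbeLayout:
    """Build a probe layout from a named preset or a coordinate table.

    Parameters
    ----------
    spec : "bright18" or a DataFrame with columns
        channel_id, x, y, z, hemisphere, region (18 rows).
    """
    if isinstance(spec, str):
        if spec != "bright18":
            raise ValueError(f"unknown layout preset {spec!r}")
        rows = []
        for region, chans in _BRIGHT18_REGIONS.items():
            hemi = "left" if region.startswith("left") else "right"
            x = -70.0 if hemi == "left" else 70.0
            for ch in chans:
                y, z = _BRIGHT18_YZ[ch if hemi == "left" else ch - 9]
                rows.append((ch, x, y, z, hemi, region))
        rows.sort()
        table = pd.DataFrame(
            rows, columns=["channel_id", "x", "y", "z", "hemisphere", "region"]
        )
    else:
        table = spec
    if len(table) != 18:
        raise ValueError(f"expected 18 channels, got {len(table)}")
    return ProbeLayout(
        channel_id=table["channel_id"].to_numpy(dtype=int),
        position=table[["x", "y", "z"]].to_numpy(dtype=float),
        hemisphere=table["hemisphere"].to_numpy(dtype=object),
        region=table["region"].to_numpy(dtype=object),
    )


def build_adjacency(layout: ProbeLayout, radius: float = 20.0) -> np.ndarray:
    """Channel adjacency: symmetric, irreflexive, distance <= radius (mm)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    d = layout.pairwise_distances()
    adj = d <= radius
    np.fill_diagonal(adj, False)
    return adj
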