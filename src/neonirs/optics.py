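"""Optical constants and the modified Beer-Lambert law (MBLL).

The MBLL relates an optical-density change at wavelength lambda to
chromophore concentration changes:

    dOD(lambda, t) = [eps_HbO(lambda) dHbO(t) + eps_HbR(lambda) dHbR(t)]
                     * d * DPF(lambda)

with concentrations in micromolar, source-detector distance ``d`` in cm,
extinction coefficients in (uM cm)^-1, and the dimensionless differential
pathlength factor DPF scaling the geometric distance to the effective
photon path. The inverse solves the 2x2 system per time sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WAVELENGTHS = (780.0, 850.0)

#: Wavelength-dependent differential pathlength factors for infant tissue.
DPF = {780.0: 5.22, 850.0: 4.23}

#: Specific extinction coefficients, (uM cm)^-1, rows = (780, 850) nm,
#: columns = (HbO, HbR). Standard tabulated in-vivo values.
EXTINCTION = np.array(
    [
        [7.10e-4, 1.035e-3],  # 780 nm
        [1.097e-3, 7.81e-4],  # 850 nm
    ]
)


@dataclass(frozen=True)
class OpticalConstants:
    """Extinction matrix, DPFs and pathlength for the MBLL.

    epsilon : (2, 2) array mapping (dHbO, dHbR) in uM to dOD per unit
        pathlength at (780, 850) nm, units (uM cm)^-1.
    dpf : mapping wavelength (nm) -> differential pathlength factor.
    d : source-detector distance in cm (default 2).
    """

    epsilon: np.ndarray = field(default_factory=lambda: EXTINCTION.copy())
    dpf: dict = field(default_factory=lambda: dict(DPF))
    d: float = 2.0

    def __post_init__(self) -> None:
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.shape != (2, 2) or abs(np.linalg.det(eps)) < 1e-12:
            raise ValueError("extinction matrix must be 2x2 and non-singular")
        if any(v <= 0 for v in self.dpf.values()) or self.d <= 0:
            raise ValueError("dpf and d must be positive")

    def pathlengths(self) -> np.ndarray:
        """Effective pathlength d * DPF(lambda) in cm, per wavelength."""
        return np.array([self.d * self.dpf[w] for w in WAVELENGTHS])


def hb_to_od(hbo: np.ndarray, hbr: np.ndarray, optics: OpticalConstants) -> np.ndarray:
    """Forward MBLL: (time, channel) Hb in uM -> (time, channel, 2) dOD."""
    hb = np.stack([hbo, hbr], axis=-1)  # (t, ch, 2)
    per_path = hb @ optics.epsilon.T  # (t, ch, lambda)
    return per_path * optics.pathlengths()


def od_to_hb_arrays(od: np.ndarray, optics: OpticalConstants) -> tuple[np.ndarray, np.ndarray]:
    """Inverse MBLL: (time, channel, 2) dOD -> (dHbO, dHbR) in uM."""
    if od.ndim != 3 or od.shape[-1] != 2:
        raise ValueError("expected (time, channel, 2) OD with both wavelengths")
    scaled = od / optics.pathlengths()
    inv = np.linalg.inv(optics.epsilon)
    hb = scaled @ inv.T
    return hb[..., 0], hb[..., 1]
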