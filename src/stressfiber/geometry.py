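"""Small geometric helpers shared by construction and calibration."""

from __future__ import annotations

import math
from typing import List, Tuple

import numpy as np

__all__ = ["hex_lattice_points", "anchor_axial_offsets"]


def hex_lattice_points(n: int, spacing: float) -> np.ndarray:
    """First ``n`` points of a hexagonal lattice, sorted by radius then angle.

    Returns an (n, 2) array centred on the origin; nearest-neighbour
    distance equals ``spacing``.
    """
    if n < 1:
        raise ValueError("need at least one point")
    reach = int(math.ceil(math.sqrt(n))) + 2
    a1 = np.array([spacing, 0.0])
    a2 = np.array([0.5 * spacing, 0.5 * math.sqrt(3.0) * spacing])
    pts: List[Tuple[float, float, float, float]] = []
    for i in range(-reach, reach + 1):
        for j in range(-reach, reach + 1):
            p = i * a1 + j * a2
            r = float(np.hypot(p[0], p[1]))
            theta = math.atan2(p[1], p[0]) % (2 * math.pi)
            pts.append((r, theta, p[0], p[1]))
    pts.sort()
    sel = pts[:n]
    return np.array([[x, y] for _, _, x, y in sel])


def anchor_axial_offsets(n: int, spacing: float, fa_rest_length: float) -> np.ndarray:
    """Axial distance of each anchor bead from its FA point.

    Anchors sit on the sphere of radius ``fa_rest_length`` around the FA
    point at the lateral lattice positions, so their axial offset is
    sqrt(l0^2 - r^2) (anchors further out sit less deep along the axis).
    """
    lat = hex_lattice_points(n, spacing)
    r2 = np.sum(lat ** 2, axis=1)
    l2 = fa_rest_length ** 2
    if np.any(r2 >= l2):
        raise ValueError(
            "anchor lattice extends beyond the FA attachment rest length; "
            "reduce the lattice spacing or the filament count"
        )
    return np.sqrt(l2 - r2)
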