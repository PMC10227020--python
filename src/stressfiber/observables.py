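"""Per-frame measurements: contractility, composition, overlap, and the
radial density of binding-site pair distances.

Conventions (documented because the literature leaves them open):

* ``F_FA`` is the *collective* stretching force of one FA site -- the sum
  of the magnitudes of its attachment-spring tensions -- reported as the
  mean of the two sites.  The net vector force is exported alongside.
* ``E_FA`` sums the attachment-spring energies of *both* sites and equals
  the mechanics fa_attachment energy term exactly.
* ``d_overlap`` is the tip-extent intersection of the two bundles
  projected on the FA--FA axis: furthest tip of the near bundle minus
  nearest tip of the far bundle; negative values are reported as 0 with a
  gap flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial.distance import pdist

from .mechanics import EnergyBreakdown, total_energy
from .state import SystemState

__all__ = [
    "ObservableFrame",
    "RadialDensity",
    "focal_adhesion_force",
    "focal_adhesion_energy",
    "overlap_distance",
    "binding_site_rdf",
    "window_mass",
    "mean_filament_length",
    "measure_frame",
]


@dataclass
class ObservableFrame:
    t: float
    F_FA: float                  # pN, mean of the two per-site collective forces
    F_FA_site: Tuple[float, float]
    F_FA_net: Tuple[float, float]  # |net vector force| per site, for comparison
    E_FA: float                  # pN*nm, both sites
    energy: EnergyBreakdown
    n_bound_linkers: int
    n_bound_motors: int
    mean_filament_length: float  # nm
    d_overlap: float             # nm (clipped at 0)
    gap: bool                    # True when the bundles do not interdigitate
    free_g_actin: int
    free_linker: int
    free_motor: int

    def to_row(self) -> Dict[str, float]:
        e = self.energy
        return {
            "t": self.t,
            "F_FA": self.F_FA,
            "F_FA_site0": self.F_FA_site[0],
            "F_FA_site1": self.F_FA_site[1],
            "F_FA_net0": self.F_FA_net[0],
            "F_FA_net1": self.F_FA_net[1],
            "E_FA": self.E_FA,
            "E_total": e.total,
            "E_filament_stretching": e.filament_stretching,
            "E_filament_bending": e.filament_bending,
            "E_motor_stretching": e.motor_stretching,
            "E_linker_stretching": e.linker_stretching,
            "E_excluded_volume": e.excluded_volume,
            "E_boundary": e.boundary,
            "n_bound_linkers": self.n_bound_linkers,
            "n_bound_motors": self.n_bound_motors,
            "mean_filament_length": self.mean_filament_length,
            "d_overlap": self.d_overlap,
            "gap": int(self.gap),
            "free_g_actin": self.free_g_actin,
            "free_linker": self.free_linker,
            "free_motor": self.free_motor,
        }


@dataclass
class RadialDensity:
    bin_edges: np.ndarray        # nm, len n_bins + 1
    values: np.ndarray           # P(r), nm^-3, len n_bins
    n_pairs: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def argmax_r(self) -> float:
        """Centre of the bin where P(r) is maximal."""
        return float(self.bin_centers[int(np.argmax(self.values))])

    def normalization_integral(self) -> float:
        r = self.bin_centers
        dr = np.diff(self.bin_edges)
        return float(np.sum(4.0 * np.pi * r ** 2 * self.values * dr))


# ----------------------------------------------------------------------
def _fa_spring_vectors(state: SystemState, site_id: int):
    site = state.fa_sites[site_id]
    vecs = []
    for fid in sorted(site.attached):
        f = state.filaments[fid]
        vecs.append(f.beads[0] - site.position)
    return np.asarray(vecs) if vecs else np.zeros((0, 3))


def focal_adhesion_force(state: SystemState, site_id: Optional[int] = None) -> float:
    """Collective stretching force on an FA site: sum_i |k (l_i - l0)|.

    With ``site_id=None`` returns the mean of the two sites (the headline
    contractility readout).
    """
    p = state.params
    if site_id is None:
        return 0.5 * (focal_adhesion_force(state, 0) + focal_adhesion_force(state, 1))
    v = _fa_spring_vectors(state, site_id)
    if not len(v):
        return 0.0
    L = np.linalg.norm(v, axis=1)
    return float(np.sum(np.abs(p.fa_spring_k * (L - p.fa_rest_length))))


def net_adhesion_force(state: SystemState, site_id: int) -> float:
    """Magnitude of the net vector spring force on one FA site."""
    p = state.params
    v = _fa_spring_vectors(state, site_id)
    if not len(v):
        return 0.0
    L = np.maximum(np.linalg.norm(v, axis=1), 1e-12)
    f = (p.fa_spring_k * (L - p.fa_rest_length) / L)[:, None] * v
    return float(np.linalg.norm(f.sum(axis=0)))


def focal_adhesion_energy(state: SystemState) -> float:
    """Elastic energy of all FA attachment springs (both sites)."""
    p = state.params
    total = 0.0
    for sid in range(len(state.fa_sites)):
        v = _fa_spring_vectors(state, sid)
        if len(v):
            L = np.linalg.norm(v, axis=1)
            total += float(0.5 * p.fa_spring_k * np.sum((L - p.fa_rest_length) ** 2))
    return total


def overlap_distance(state: SystemState) -> Tuple[float, bool]:
    """Tip-extent overlap of the two bundles along the FA--FA axis.

    Returns ``(overlap, gap)``; ``gap`` is True when the bundles have not
    yet met (overlap clipped at 0).
    """
    axis = state.fa_sites[1].position - state.fa_sites[0].position
    axis = axis / np.linalg.norm(axis)
    tips0 = [float(np.dot(state.filaments[fid].tip, axis))
             for fid in state.bundle_filaments(0)]
    tips1 = [float(np.dot(state.filaments[fid].tip, axis))
             for fid in state.bundle_filaments(1)]
    if not tips0 or not tips1:
        return 0.0, True
    raw = max(tips0) - min(tips1)
    return (max(0.0, raw), raw <= 0.0)


def mean_filament_length(state: SystemState) -> float:
    rise = state.params.monomer_rise
    if not state.filaments:
        return 0.0
    return float(np.mean([f.contour_length(rise) for f in state.filaments.values()]))


# ----------------------------------------------------------------------
def binding_site_rdf(state: SystemState, bin_edges: Optional[np.ndarray] = None
                     ) -> RadialDensity:
    """Radial probability density of inter-filament binding-site distances.

    Every hinge point is a candidate binding site; all pairs on *different*
    filaments are binned by distance, each bin divided by its shell volume
    4 pi r^2 dr, and the result normalized so that
    integral 4 pi r^2 P(r) dr = 1.
    """
    if len(state.filaments) < 2:
        raise ValueError("need at least two filaments for the pair density")
    if bin_edges is None:
        bin_edges = np.arange(0.0, 302.0, 2.0)
    pts, labels = state.hinge_points()
    fil = np.asarray([l[0] for l in labels], dtype=float)
    d = pdist(pts)
    same = pdist(fil[:, None]) == 0
    d = d[~same]
    return rdf_from_distances(d, bin_edges)


def rdf_from_distances(distances: np.ndarray, bin_edges: np.ndarray) -> RadialDensity:
    hist, edges = np.histogram(distances, bins=bin_edges)
    r = 0.5 * (edges[:-1] + edges[1:])
    dr = np.diff(edges)
    total = hist.sum()
    if total == 0:
        return RadialDensity(edges, np.zeros(len(r)), 0)
    P = hist / total / (4.0 * np.pi * r ** 2 * dr)
    return RadialDensity(edges, P, int(total))


def window_mass(rdf: RadialDensity, r_lo: float, r_hi: float) -> float:
    """Plain sum of P(r) over the bins whose centres lie in [r_lo, r_hi]."""
    if r_lo >= r_hi:
        raise ValueError("window requires r_lo < r_hi")
    if r_lo < rdf.bin_edges[0] or r_hi > rdf.bin_edges[-1]:
        raise ValueError("window outside the binned range")
    c = rdf.bin_centers
    sel = (c >= r_lo) & (c <= r_hi)
    return float(np.sum(rdf.values[sel]))


def measure_frame(state: SystemState) -> ObservableFrame:
    d_ov, gap = overlap_distance(state)
    return ObservableFrame(
        t=state.t,
        F_FA=focal_adhesion_force(state),
        F_FA_site=(focal_adhesion_force(state, 0), focal_adhesion_force(state, 1)),
        F_FA_net=(net_adhesion_force(state, 0), net_adhesion_force(state, 1)),
        E_FA=focal_adhesion_energy(state),
        energy=total_energy(state),
        n_bound_linkers=len(state.linkers),
        n_bound_motors=len(state.motors),
        mean_filament_length=mean_filament_length(state),
        d_overlap=d_ov,
        gap=gap,
        free_g_actin=state.free_g_actin,
        free_linker=state.free_linker,
        free_motor=state.free_motor,
    )
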