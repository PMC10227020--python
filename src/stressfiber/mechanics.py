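"""Mechanical energy terms, analytic forces, and energy minimization.

The network energy is a sum of harmonic cylinder stretching, a
(1 - cos theta) bending penalty at filament hinge points, harmonic
crosslinker / motor / focal-adhesion springs, a finite-range pairwise
excluded-volume repulsion between filament segments, and a short-range
repulsive boundary layer at the box faces.  Forces are analytic; the
mechanics is quasi-static: after every chemistry slice the energy is
relaxed by nonlinear conjugate-gradient minimization with the FA anchor
points held fixed.

All terms are evaluated vectorized over a flattened coordinate vector; a
:class:`MechContext` caches the index arrays so repeated evaluations
inside one minimization are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial import cKDTree

from . import _kernel
from .state import SystemState

#: set True to force the pure-numpy energy/gradient path (used by tests to
#: cross-check the compiled kernel against the reference implementation)
FORCE_NUMPY = False

__all__ = [
    "EnergyBreakdown",
    "stretch_energy",
    "bend_energy",
    "excluded_volume_energy",
    "segment_segment_distance",
    "total_energy",
    "forces",
    "minimize",
    "MinimizeInfo",
]

_EPS = 1e-12


@dataclass
class EnergyBreakdown:
    filament_stretching: float = 0.0
    filament_bending: float = 0.0
    motor_stretching: float = 0.0
    linker_stretching: float = 0.0
    excluded_volume: float = 0.0
    fa_attachment: float = 0.0
    boundary: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.filament_stretching + self.filament_bending
            + self.motor_stretching + self.linker_stretching
            + self.excluded_volume + self.fa_attachment + self.boundary
        )


# ----------------------------------------------------------------------
# Elementary terms (scalar reference implementations used by tests).

def stretch_energy(length: float, rest: float, k: float) -> float:
    """Harmonic penalty 1/2 k (l - l0)^2 for a cylinder or spring."""
    if length < 0:
        raise ValueError("length must be non-negative")
    if rest <= 0 or k <= 0:
        raise ValueError("rest length and spring constant must be positive")
    return 0.5 * k * (length - rest) ** 2


def bend_energy(triplet, k_bend: float) -> float:
    """k_bend (1 - cos theta) between consecutive cylinder axes."""
    a, b, c = (np.asarray(p, dtype=float) for p in triplet)
    u, v = b - a, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _EPS or nv < _EPS:
        raise ValueError("coincident beads in bending triplet")
    cos = float(np.dot(u, v) / (nu * nv))
    return k_bend * (1.0 - min(1.0, max(-1.0, cos)))


def segment_segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between segments [p1,q1] and [p2,q2]."""
    d = _segment_pair_geometry(
        np.asarray(p1, float)[None], np.asarray(q1, float)[None],
        np.asarray(p2, float)[None], np.asarray(q2, float)[None],
    )[0]
    return float(d[0])


def excluded_volume_energy(p1, q1, p2, q2, k_ev: float, cutoff: float) -> float:
    """Repulsion 1/2 k (cutoff - d)^2 for segment pairs closer than cutoff."""
    d = segment_segment_distance(p1, q1, p2, q2)
    if d >= cutoff:
        return 0.0
    return 0.5 * k_ev * (cutoff - d) ** 2


# ----------------------------------------------------------------------
# Vectorized geometry helpers.

def _segment_pair_geometry(P1, Q1, P2, Q2):
    """Closest-approach distance and parameters for segment pair arrays.

    Returns (dist, s, t, u) with closest points P1 + s*(Q1-P1) and
    P2 + t*(Q2-P2), u the unit vector from pair-2 point to pair-1 point.
    """
    d1 = Q1 - P1
    d2 = Q2 - P2
    r = P1 - P2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)
    denom = a * e - b * b
    s = np.where(denom > _EPS, (b * f - c * e) / np.where(denom > _EPS, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    t = np.where(e > _EPS, (b * s + f) / np.where(e > _EPS, e, 1.0), 0.0)
    t_clamped = np.clip(t, 0.0, 1.0)
    # re-project s where t was clamped
    need = t != t_clamped
    if np.any(need):
        s_new = np.where(a > _EPS, (b * t_clamped - c) / np.where(a > _EPS, a, 1.0), 0.0)
        s = np.where(need, np.clip(s_new, 0.0, 1.0), s)
    t = t_clamped
    cp1 = P1 + s[:, None] * d1
    cp2 = P2 + t[:, None] * d2
    diff = cp1 - cp2
    dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    safe = np.where(dist > _EPS, dist, 1.0)
    u = diff / safe[:, None]
    return dist, s, t, u



def _scatter_add(grad: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    """grad[idx] += vals, via bincount (faster than ufunc.at for our sizes)."""
    n = grad.shape[0]
    for c in range(3):
        grad[:, c] += np.bincount(idx, weights=vals[:, c], minlength=n)


# ----------------------------------------------------------------------
class MechContext:
    """Flattened view of a SystemState for fast energy/gradient evaluation."""

    def __init__(self, state: SystemState, ev_margin: float = 20.0):
        p = state.params
        self.params = p
        self.fil_ids = sorted(state.filaments)
        self.offsets = {}
        pos: List[np.ndarray] = []
        n = 0
        for fid in self.fil_ids:
            f = state.filaments[fid]
            self.offsets[fid] = n
            pos.append(f.beads)
            n += f.n_beads
        self.n_beads = n
        self.x0 = np.concatenate(pos, axis=0) if pos else np.zeros((0, 3))

        # cylinders (stretching) ------------------------------------------------
        ci, cj, crest, cfil = [], [], [], []
        bi, bj, bk = [], [], []
        for fid in self.fil_ids:
            f = state.filaments[fid]
            off = self.offsets[fid]
            rests = f.rest_lengths(p.monomer_rise)
            for s in range(f.n_beads - 1):
                ci.append(off + s)
                cj.append(off + s + 1)
                crest.append(max(rests[s], p.monomer_rise))
                cfil.append(fid)
            for s in range(1, f.n_beads - 1):
                bi.append(off + s - 1)
                bj.append(off + s)
                bk.append(off + s + 1)
        self.cyl_i = np.asarray(ci, dtype=int)
        self.cyl_j = np.asarray(cj, dtype=int)
        self.cyl_rest = np.asarray(crest, dtype=float)
        self.cyl_fil = np.asarray(cfil, dtype=int)
        self.bend_i = np.asarray(bi, dtype=int)
        self.bend_j = np.asarray(bj, dtype=int)
        self.bend_k = np.asarray(bk, dtype=int)

        # FA springs ------------------------------------------------------------
        fa_bead, fa_pos = [], []
        for site in state.fa_sites:
            for fid in sorted(site.attached):
                fa_bead.append(self.offsets[fid])  # bead 0 is the anchored plus end
                fa_pos.append(site.position)
        self.fa_bead = np.asarray(fa_bead, dtype=int)
        self.fa_pos = np.asarray(fa_pos, dtype=float) if fa_pos else np.zeros((0, 3))

        # linker / motor springs --------------------------------------------------
        self.link_idx, self.link_frac, self.link_ids = self._spring_table(state, state.linkers)
        self.mot_idx, self.mot_frac, self.mot_ids = self._spring_table(state, state.motors)

        # excluded-volume candidate pairs (rebuilt per context, with margin) ------
        self._build_ev_pairs(ev_margin)

    def _spring_table(self, state: SystemState, table):
        idx, frac, ids = [], [], []
        rise = state.params.monomer_rise
        for eid in sorted(table):
            e = table[eid]
            row_i, row_f = [], []
            for fi, arc in e.ends:
                f = state.filaments[fi]
                j, fr = f.locate(arc, rise)
                off = self.offsets[fi]
                row_i.extend([off + j, off + j + 1])
                row_f.append(fr)
            idx.append(row_i)
            frac.append(row_f)
            ids.append(eid)
        if not idx:
            return (np.zeros((0, 4), dtype=int), np.zeros((0, 2)), [])
        return np.asarray(idx, dtype=int), np.asarray(frac, dtype=float), ids

    def _build_ev_pairs(self, margin: float) -> None:
        # two-stage neighbour list: coarse midpoint query, then exact
        # segment distances; the margin covers bead motion within one
        # minimization call (the list is rebuilt per call)
        p = self.params
        empty = np.zeros(0, dtype=int)
        if len(self.cyl_i) < 2:
            self.ev_a, self.ev_b = empty, empty
            return
        x = self.x0
        mids = 0.5 * (x[self.cyl_i] + x[self.cyl_j])
        seg_len = np.linalg.norm(x[self.cyl_j] - x[self.cyl_i], axis=1)
        radius = p.ev_cutoff + margin + float(seg_len.max())
        tree = cKDTree(mids)
        pairs = tree.query_pairs(radius, output_type="ndarray")
        if len(pairs) == 0:
            self.ev_a, self.ev_b = empty, empty
            return
        a, b = pairs[:, 0], pairs[:, 1]
        same_fil = self.cyl_fil[a] == self.cyl_fil[b]
        adjacent = same_fil & (np.abs(a - b) <= 1)
        a, b = a[~adjacent], b[~adjacent]
        if len(a):
            dist, _, _, _ = _segment_pair_geometry(
                x[self.cyl_i[a]], x[self.cyl_j[a]],
                x[self.cyl_i[b]], x[self.cyl_j[b]])
            close = dist < p.ev_cutoff + margin
            a, b = a[close], b[close]
        self.ev_a = a
        self.ev_b = b
        self._finalize_kernel_arrays()

    def _finalize_kernel_arrays(self) -> None:
        self.ev_ai = self.cyl_i[self.ev_a].astype(np.int64)
        self.ev_aj = self.cyl_j[self.ev_a].astype(np.int64)
        self.ev_bi = self.cyl_i[self.ev_b].astype(np.int64)
        self.ev_bj = self.cyl_j[self.ev_b].astype(np.int64)
        self.box_arr = np.asarray(self.params.box, dtype=float)

    # ------------------------------------------------------------------
    def energy_terms(self, xflat: np.ndarray) -> EnergyBreakdown:
        e, _ = self._eval(xflat, want_grad=False)
        return e

    def energy_and_grad(self, xflat: np.ndarray):
        e, g = self._eval(xflat, want_grad=True)
        return e.total, g

    def _eval(self, xflat: np.ndarray, want_grad: bool):
        p = self.params
        if _kernel.HAVE_NUMBA and not FORCE_NUMPY:
            x = np.ascontiguousarray(xflat.reshape(-1, 3))
            terms, grad = _kernel.eval_energy_grad(
                x,
                self.cyl_i, self.cyl_j, self.cyl_rest, p.k_filament_stretch,
                self.bend_i, self.bend_j, self.bend_k, p.k_filament_bend,
                self.fa_bead, self.fa_pos, p.fa_spring_k, p.fa_rest_length,
                self.link_idx, self.link_frac, p.linker_spring_k,
                p.linker_rest_length,
                self.mot_idx, self.mot_frac, p.motor_spring_k,
                p.motor_rest_length,
                self.ev_ai, self.ev_aj, self.ev_bi, self.ev_bj,
                p.ev_k, p.ev_cutoff,
                self.box_arr, p.boundary_range, p.boundary_k,
                want_grad,
            )
            eb = EnergyBreakdown(
                filament_stretching=float(terms[0]),
                filament_bending=float(terms[1]),
                motor_stretching=float(terms[2]),
                linker_stretching=float(terms[3]),
                excluded_volume=float(terms[4]),
                fa_attachment=float(terms[5]),
                boundary=float(terms[6]),
            )
            return eb, (grad.ravel() if want_grad else None)
        x = xflat.reshape(-1, 3)
        grad = np.zeros_like(x) if want_grad else None
        eb = EnergyBreakdown()

        # filament stretching
        if len(self.cyl_i):
            d = x[self.cyl_j] - x[self.cyl_i]
            L = np.linalg.norm(d, axis=1)
            dL = L - self.cyl_rest
            eb.filament_stretching = float(0.5 * p.k_filament_stretch * np.sum(dL * dL))
            if want_grad:
                u = d / np.maximum(L, _EPS)[:, None]
                g = p.k_filament_stretch * dL[:, None] * u
                _scatter_add(grad, self.cyl_j, g)
                _scatter_add(grad, self.cyl_i, -g)

        # filament bending
        if len(self.bend_j):
            u = x[self.bend_j] - x[self.bend_i]
            v = x[self.bend_k] - x[self.bend_j]
            nu = np.maximum(np.linalg.norm(u, axis=1), _EPS)
            nv = np.maximum(np.linalg.norm(v, axis=1), _EPS)
            a = u / nu[:, None]
            b = v / nv[:, None]
            cos = np.clip(np.einsum("ij,ij->i", a, b), -1.0, 1.0)
            eb.filament_bending = float(p.k_filament_bend * np.sum(1.0 - cos))
            if want_grad:
                dc_du = (b - cos[:, None] * a) / nu[:, None]
                dc_dv = (a - cos[:, None] * b) / nv[:, None]
                kb = p.k_filament_bend
                _scatter_add(grad, self.bend_i, kb * dc_du)
                _scatter_add(grad, self.bend_j, kb * (dc_dv - dc_du))
                _scatter_add(grad, self.bend_k, -kb * dc_dv)

        # FA attachment springs
        if len(self.fa_bead):
            d = x[self.fa_bead] - self.fa_pos
            L = np.linalg.norm(d, axis=1)
            dL = L - p.fa_rest_length
            eb.fa_attachment = float(0.5 * p.fa_spring_k * np.sum(dL * dL))
            if want_grad:
                u = d / np.maximum(L, _EPS)[:, None]
                _scatter_add(grad, self.fa_bead, p.fa_spring_k * dL[:, None] * u)

        # linker and motor springs
        for idx, frac, k, rest, attr in (
            (self.link_idx, self.link_frac, p.linker_spring_k, p.linker_rest_length,
             "linker_stretching"),
            (self.mot_idx, self.mot_frac, p.motor_spring_k, p.motor_rest_length,
             "motor_stretching"),
        ):
            if not len(idx):
                continue
            f1 = frac[:, 0][:, None]
            f2 = frac[:, 1][:, None]
            pA = (1 - f1) * x[idx[:, 0]] + f1 * x[idx[:, 1]]
            pB = (1 - f2) * x[idx[:, 2]] + f2 * x[idx[:, 3]]
            d = pA - pB
            L = np.maximum(np.linalg.norm(d, axis=1), _EPS)
            dL = L - rest
            setattr(eb, attr, float(0.5 * k * np.sum(dL * dL)))
            if want_grad:
                u = d / L[:, None]
                g = k * dL[:, None] * u
                _scatter_add(grad, idx[:, 0], (1 - f1) * g)
                _scatter_add(grad, idx[:, 1], f1 * g)
                _scatter_add(grad, idx[:, 2], -(1 - f2) * g)
                _scatter_add(grad, idx[:, 3], -f2 * g)

        # excluded volume between filament segments
        if len(self.ev_a):
            P1 = x[self.cyl_i[self.ev_a]]
            Q1 = x[self.cyl_j[self.ev_a]]
            P2 = x[self.cyl_i[self.ev_b]]
            Q2 = x[self.cyl_j[self.ev_b]]
            dist, s, t, u = _segment_pair_geometry(P1, Q1, P2, Q2)
            pen = p.ev_cutoff - dist
            act = pen > 0
            if np.any(act):
                pen = pen[act]
                eb.excluded_volume = float(0.5 * p.ev_k * np.sum(pen * pen))
                if want_grad:
                    g = (-p.ev_k * pen)[:, None] * u[act]  # dE/d(closest point 1)
                    sa = s[act][:, None]
                    ta = t[act][:, None]
                    ia = self.ev_a[act]
                    ib = self.ev_b[act]
                    _scatter_add(grad, self.cyl_i[ia], (1 - sa) * g)
                    _scatter_add(grad, self.cyl_j[ia], sa * g)
                    _scatter_add(grad, self.cyl_i[ib], -(1 - ta) * g)
                    _scatter_add(grad, self.cyl_j[ib], -ta * g)

        # boundary repulsion
        lo = p.boundary_range - x                      # >0 when inside the layer
        hi = x - (np.asarray(p.box) - p.boundary_range)
        pen_lo = np.maximum(lo, 0.0)
        pen_hi = np.maximum(hi, 0.0)
        eb.boundary = float(0.5 * p.boundary_k * (np.sum(pen_lo ** 2) + np.sum(pen_hi ** 2)))
        if want_grad:
            grad += p.boundary_k * (pen_hi - pen_lo)

        return eb, (grad.ravel() if want_grad else None)

    def write_back(self, state: SystemState, xflat: np.ndarray) -> None:
        x = xflat.reshape(-1, 3)
        for fid in self.fil_ids:
            f = state.filaments[fid]
            off = self.offsets[fid]
            f.beads = x[off:off + f.n_beads].copy()


# ----------------------------------------------------------------------
def total_energy(state: SystemState) -> EnergyBreakdown:
    """Evaluate every mechanical energy term of the current configuration."""
    ctx = MechContext(state)
    return ctx.energy_terms(ctx.x0.ravel())


def forces(state: SystemState) -> np.ndarray:
    """Analytic forces F = -grad E, one 3-vector per bead (context order)."""
    ctx = MechContext(state)
    _, g = ctx.energy_and_grad(ctx.x0.ravel())
    return -g.reshape(-1, 3)


@dataclass
class MinimizeInfo:
    converged: bool
    iterations: int
    energy_before: float
    energy_after: float
    max_residual_force: float


def minimize(
    state: SystemState,
    force_tol: Optional[float] = None,
    maxiter: Optional[int] = None,
) -> MinimizeInfo:
    """Relax the network by conjugate-gradient energy minimization (in place).

    FA anchor points are fixed; only bead positions move.  The chemical
    composition is untouched.  Convergence means the infinity-norm of the
    residual gradient is below ``force_tol`` (pN).
    """
    p = state.params
    tol = p.force_tol if force_tol is None else force_tol
    cap = p.cg_maxiter if maxiter is None else maxiter
    ctx = MechContext(state)
    if ctx.n_beads == 0:
        return MinimizeInfo(True, 0, 0.0, 0.0, 0.0)
    x0 = ctx.x0.ravel().copy()
    e0, g0 = ctx.energy_and_grad(x0)
    if not np.isfinite(e0):
        raise FloatingPointError("non-finite mechanical energy before minimization")
    if np.abs(g0).max() <= tol:
        return MinimizeInfo(True, 0, e0, e0, float(np.abs(g0).max()))

    res = _scipy_minimize(
        ctx.energy_and_grad, x0, jac=True, method="CG",
        options={"gtol": tol, "maxiter": cap, "norm": np.inf},
    )
    xf, ef = res.x, float(res.fun)
    if not np.isfinite(ef) or ef > e0:
        # line-search failure: keep the better of start/end
        xf, ef = x0, e0
    _, gf = ctx.energy_and_grad(xf)
    resid = float(np.abs(gf).max())
    ctx.write_back(state, xf)
    return MinimizeInfo(resid <= tol, int(res.nit), e0, ef, resid)
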