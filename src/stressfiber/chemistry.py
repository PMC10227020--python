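"""Stochastic chemistry: rate laws and the Next Reaction Method engine.

Reaction channels
-----------------
* filament polymerization / depolymerization at the dynamic tip
  (growth propensity proportional to the free G-actin count),
* crosslinker binding between eligible hinge-site pairs and force-dependent
  unbinding (slip bond: faster under tension),
* motor binding, force-dependent unbinding (catch bond: slower under
  tension), and walking with a linear force--velocity relation that stalls
  at ``F_stall``.

Binding sites are the filament hinge points (beads); the same convention
is used by the radial density observable.  Diffusing species are
well-mixed and tracked only by molecule counts.

The scheduler is an exact Next Reaction Method (per-channel exponential
clocks in a priority queue, Gibson--Bruck rescaling when propensities
change).  Channels with identical propensities that differ only by which
entity they act on (the polymerization tips sharing one G-actin pool, the
equal-rate binding candidates) are aggregated into one channel whose
firing picks the entity uniformly -- an exact, faster equivalent that is
cross-checked against a per-channel direct-method oracle in the tests.
Because all rates are frozen between mechanics synchronization points and
exponential clocks are memoryless, the engine is rebuilt at every sync
with fresh clocks, which leaves the sampled law unchanged.
"""

from __future__ import annotations

import heapq
import math
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .params import Parameters
from .state import BoundLinker, BoundMotor, SystemState

__all__ = [
    "linker_unbind_rate",
    "linker_bind_candidates",
    "motor_bind_candidates",
    "motor_unbind_rate",
    "motor_walk_rate",
    "motor_walk",
    "polymerize",
    "depolymerize",
    "bind_pair",
    "release_entity",
    "NextReactionScheduler",
    "ChemistryEngine",
    "nrm_advance",
]


# ----------------------------------------------------------------------
# Mechanosensitive rate laws (Bell slip/catch, linear force--velocity).

def linker_unbind_rate(F: float, p: Parameters) -> float:
    """Slip-bond unbinding: chi * k_off * exp(F x_slip / kT), F >= 0 in pN."""
    if F < 0:
        raise ValueError("force must be non-negative")
    return p.chi * p.k_off_linker * math.exp(F * p.x_slip / p.kT)


def motor_unbind_rate(F: float, p: Parameters) -> float:
    """Catch-bond unbinding: k_off * exp(-F / F_catch), decreasing in F."""
    if F < 0:
        raise ValueError("force must be non-negative")
    return p.k_off_motor * math.exp(-F / p.F_catch)


def motor_walk_rate(F: float, p: Parameters) -> float:
    """Walk rate in steps/s: (v0/step) * max(0, 1 - F/F_stall)."""
    if F < 0:
        raise ValueError("force must be non-negative")
    return (p.v_walk0 / p.motor_step) * max(0.0, 1.0 - F / p.F_stall)


# ----------------------------------------------------------------------
# Site indexing and candidate pairs.

class _SiteIndex:
    """Global integer ids for every hinge site, in deterministic order."""

    def __init__(self, state: SystemState):
        self.offsets: Dict[int, int] = {}
        self.counts: Dict[int, int] = {}
        pts, fil, bead = [], [], []
        n = 0
        for fid in sorted(state.filaments):
            f = state.filaments[fid]
            self.offsets[fid] = n
            self.counts[fid] = f.n_beads
            pts.append(f.beads)
            fil.extend([fid] * f.n_beads)
            bead.extend(range(f.n_beads))
            n += f.n_beads
        self.n = n
        self.pts = np.concatenate(pts, axis=0) if pts else np.zeros((0, 3))
        self.fil = np.asarray(fil, dtype=int)
        self.bead = np.asarray(bead, dtype=int)

    def gidx(self, site: Tuple[int, int]) -> int:
        return self.offsets[site[0]] + site[1]

    def gidx_or_none(self, site: Tuple[int, int]) -> Optional[int]:
        """Global id, or None for beads created after this index was built."""
        fid, bead = site
        off = self.offsets.get(fid)
        if off is None or bead >= self.counts[fid]:
            return None
        return off + bead

    def site(self, g: int) -> Tuple[int, int]:
        return (int(self.fil[g]), int(self.bead[g]))

    def pairs_in_window(self, window: Tuple[float, float]) -> np.ndarray:
        """(K, 2) global-index pairs on different filaments within window."""
        lo, hi = window
        if self.n < 2:
            return np.zeros((0, 2), dtype=np.int64)
        tree = cKDTree(self.pts)
        pairs = tree.query_pairs(hi, output_type="ndarray")
        if len(pairs) == 0:
            return np.zeros((0, 2), dtype=np.int64)
        a, b = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(self.pts[a] - self.pts[b], axis=1)
        keep = (self.fil[a] != self.fil[b]) & (d >= lo) & (d <= hi)
        out = pairs[keep].astype(np.int64)
        # deterministic ordering regardless of KDTree internals
        order = np.lexsort((out[:, 1], out[:, 0]))
        return out[order]


def _candidate_site_pairs(state: SystemState, window) -> List[tuple]:
    idx = _SiteIndex(state)
    pairs = idx.pairs_in_window(window)
    return [(idx.site(a), idx.site(b)) for a, b in pairs]


def linker_bind_candidates(state: SystemState):
    """Eligible (site_i, site_j) crosslinker pairs with per-pair propensities.

    Sites already occupied by a bound linker or motor endpoint are excluded;
    every eligible pair carries propensity chi * k_on_linker * n_free.
    """
    p = state.params
    a = p.chi * p.k_on_linker * state.free_linker
    occ = state.occupied_sites("linker")
    return [
        (si, sj, a)
        for si, sj in _candidate_site_pairs(state, p.linker_binding_window)
        if si not in occ and sj not in occ
    ]


def motor_bind_candidates(state: SystemState):
    p = state.params
    a = p.k_on_motor * state.free_motor
    occ = state.occupied_sites("motor")
    return [
        (si, sj, a)
        for si, sj in _candidate_site_pairs(state, p.motor_binding_window)
        if si not in occ and sj not in occ
    ]


class _PairSet:
    """Uniform sampling over candidate pairs with O(deg) (in)validation.

    Pair validity = both endpoint sites unoccupied; a CSR incidence index
    maps a site to the pairs it participates in.
    """

    def __init__(self, pairs: np.ndarray, n_sites: int, occupied_gidx):
        self.pairs = pairs
        K = len(pairs)
        inc = np.concatenate([pairs[:, 0], pairs[:, 1]]) if K else np.zeros(0, int)
        pid = np.concatenate([np.arange(K), np.arange(K)])
        order = np.argsort(inc, kind="stable")
        self._sorted_pid = pid[order]
        self._indptr = np.searchsorted(inc[order], np.arange(n_sites + 1))
        self.blocked = np.zeros(K, dtype=np.int16)
        self.n_valid = K
        for g in occupied_gidx:
            self.occupy(g)

    def __len__(self):
        return int(self.n_valid)

    def _rows(self, g: int) -> np.ndarray:
        return self._sorted_pid[self._indptr[g]:self._indptr[g + 1]]

    def occupy(self, g: int) -> None:
        r = self._rows(g)
        if len(r):
            before = self.blocked[r]
            self.n_valid -= int(np.count_nonzero(before == 0))
            self.blocked[r] = before + 1

    def free(self, g: int) -> None:
        r = self._rows(g)
        if len(r):
            before = self.blocked[r]
            self.blocked[r] = before - 1
            self.n_valid += int(np.count_nonzero(before == 1))

    def sample(self, rng: np.random.Generator) -> Tuple[int, int]:
        if self.n_valid <= 0:
            raise RuntimeError("sampling from an empty candidate set")
        K = len(self.pairs)
        while True:  # rejection against the occupancy mask; uniform over valid
            i = int(rng.integers(K))
            if self.blocked[i] == 0:
                return int(self.pairs[i, 0]), int(self.pairs[i, 1])


# ----------------------------------------------------------------------
# Single-event state updates (also used directly by tests).

def _entity_tension(state: SystemState, entity, k: float, rest: float) -> float:
    L = state.spring_length(entity)
    return max(0.0, k * (L - rest))


def linker_tension(state: SystemState, linker: BoundLinker) -> float:
    p = state.params
    return _entity_tension(state, linker, p.linker_spring_k, p.linker_rest_length)


def motor_tension(state: SystemState, motor: BoundMotor) -> float:
    p = state.params
    return _entity_tension(state, motor, p.motor_spring_k, p.motor_rest_length)


def polymerize(state: SystemState, fil_id: int) -> None:
    """Add one monomer at the dynamic tip (new cylinder when the tip fills)."""
    if state.free_g_actin < 1:
        raise ValueError("no free G-actin to polymerize")
    p = state.params
    f = state.filaments[fil_id]
    if f.monomers[-1] >= p.monomers_per_cylinder:
        u = f.beads[-1] - f.beads[-2]
        n = np.linalg.norm(u)
        u = u / n if n > 0 else np.array([0.0, 0.0, 1.0])
        f.beads = np.vstack([f.beads, f.beads[-1] + p.monomer_rise * u])
        f.monomers.append(1)
    else:
        f.monomers[-1] += 1
    state.free_g_actin -= 1


def depolymerize(state: SystemState, fil_id: int):
    """Remove one tip monomer.

    Returns ``(released, removed_site)``: ``released`` lists
    ``(kind, entity_id, sites)`` for every linker/motor whose endpoint fell
    off the shortened tip (returned to the free pool); ``removed_site`` is
    the hinge site deleted with the tip bead, or None.
    """
    p = state.params
    f = state.filaments[fil_id]
    if sum(f.monomers) <= 1:
        raise ValueError("cannot depolymerize a 1-monomer filament")
    f.monomers[-1] -= 1
    removed_site = None
    if f.monomers[-1] == 0:
        removed_site = (fil_id, f.n_beads - 1)
        f.beads = f.beads[:-1]
        f.monomers.pop()
    state.free_g_actin += 1

    released = []
    contour = f.contour_length(p.monomer_rise)
    for kind, table in (("linker", state.linkers), ("motor", state.motors)):
        for eid in list(table):
            e = table[eid]
            if removed_site is not None and removed_site in e.sites:
                released.append((kind, eid, e.sites))
                continue
            for fi, arc in e.ends:
                if fi == fil_id and arc > contour + 1e-9:
                    released.append((kind, eid, e.sites))
                    break
    for kind, eid, _sites in released:
        release_entity(state, kind, eid)
    return released, removed_site


def release_entity(state: SystemState, kind: str, eid: int) -> None:
    table = state.linkers if kind == "linker" else state.motors
    if eid not in table:
        return
    e = table.pop(eid)
    occ = state.occupied_linker if kind == "linker" else state.occupied_motor
    for site in e.sites:
        occ.pop(site, None)
    if kind == "linker":
        state.free_linker += 1
    else:
        state.free_motor += 1


def bind_pair(state: SystemState, kind: str, site_a, site_b) -> int:
    """Create a bound linker or motor spanning two hinge sites."""
    p = state.params
    rise = p.monomer_rise
    ends = []
    for fid, bead in (site_a, site_b):
        f = state.filaments[fid]
        ends.append((fid, float(f.cum_rest(rise)[bead])))
    eid = state.new_id()
    if kind == "linker":
        if state.free_linker < 1:
            raise ValueError("no free crosslinkers")
        state.linkers[eid] = BoundLinker(eid, (ends[0], ends[1]),
                                         sites=(tuple(site_a), tuple(site_b)))
        state.free_linker -= 1
    else:
        if state.free_motor < 1:
            raise ValueError("no free motors")
        state.motors[eid] = BoundMotor(eid, (ends[0], ends[1]),
                                       sites=(tuple(site_a), tuple(site_b)))
        state.free_motor -= 1
    occ = state.occupied_linker if kind == "linker" else state.occupied_motor
    occ[tuple(site_a)] = eid
    occ[tuple(site_b)] = eid
    return eid


def motor_walk(state: SystemState, motor_id: int, end_index: int) -> None:
    """Advance one motor endpoint one step towards its filament's plus end."""
    m = state.motors[motor_id]
    fid, arc = m.ends[end_index]
    new_arc = max(0.0, arc - state.params.motor_step)
    ends = list(m.ends)
    ends[end_index] = (fid, new_arc)
    m.ends = (ends[0], ends[1])


# ----------------------------------------------------------------------
class NextReactionScheduler:
    """Exact NRM scheduler over named channels.

    Channel keys must be mutually comparable tuples; simultaneous firing
    times break ties lexicographically by key, so trajectories are a
    deterministic function of the RNG seed.
    """

    def __init__(self, rng: np.random.Generator, t0: float = 0.0):
        self.rng = rng
        self.t = t0
        self.rates: Dict[tuple, float] = {}
        self.taus: Dict[tuple, float] = {}
        self.heap: List[Tuple[float, tuple]] = []

    def add_channel(self, key: tuple, rate: float) -> None:
        if rate < 0 or not np.isfinite(rate):
            raise FloatingPointError(f"invalid propensity {rate!r} for channel {key}")
        self.rates[key] = rate
        tau = self.t + self.rng.exponential(1.0 / rate) if rate > 0 else math.inf
        self.taus[key] = tau
        if math.isfinite(tau):
            heapq.heappush(self.heap, (tau, key))

    def set_rate(self, key: tuple, rate: float) -> None:
        if rate < 0 or not np.isfinite(rate):
            raise FloatingPointError(f"invalid propensity {rate!r} for channel {key}")
        old = self.rates.get(key)
        if old is None:
            self.add_channel(key, rate)
            return
        if rate == old:
            return
        old_tau = self.taus[key]
        if rate <= 0:
            tau = math.inf
        elif old > 0 and math.isfinite(old_tau):
            tau = self.t + (old / rate) * (old_tau - self.t)
        else:
            tau = self.t + self.rng.exponential(1.0 / rate)
        self.rates[key] = rate
        self.taus[key] = tau
        if math.isfinite(tau):
            heapq.heappush(self.heap, (tau, key))

    def remove_channel(self, key: tuple) -> None:
        self.rates.pop(key, None)
        self.taus.pop(key, None)

    def next_event(self, until: float) -> Optional[tuple]:
        """Pop the next channel firing at or before ``until``; advance t."""
        while self.heap:
            tau, key = self.heap[0]
            cur = self.taus.get(key)
            if cur is None or cur != tau:
                heapq.heappop(self.heap)        # stale entry
                continue
            if tau > until:
                self.t = until
                return None
            heapq.heappop(self.heap)
            self.t = tau
            rate = self.rates.get(key, 0.0)
            if rate > 0:
                new_tau = self.t + self.rng.exponential(1.0 / rate)
                self.taus[key] = new_tau
                heapq.heappush(self.heap, (new_tau, key))
            else:
                self.taus[key] = math.inf
            return key
        self.t = until
        return None


# ----------------------------------------------------------------------
class ChemistryEngine:
    """One chemistry slice: all propensities frozen to the current geometry.

    Built after each mechanics relaxation; advances the clock by firing
    NRM events, updating force-dependent rates from the frozen bead
    positions as spring endpoints move.
    """

    POLY = ("poly", 0, 0)
    DEPOLY = ("depoly", 0, 0)
    LBIND = ("lbind", 0, 0)
    MBIND = ("mbind", 0, 0)

    def __init__(self, state: SystemState, record_events: bool = False):
        self.state = state
        self.p = state.params
        self.log: Optional[List[tuple]] = [] if record_events else None
        self.sched = NextReactionScheduler(state.rng, state.t)
        self.idx = _SiteIndex(state)
        occ_l = [self.idx.gidx(s) for s in state.occupied_sites("linker")]
        occ_m = [self.idx.gidx(s) for s in state.occupied_sites("motor")]
        self.lpairs = _PairSet(
            self.idx.pairs_in_window(self.p.linker_binding_window), self.idx.n,
            occ_l)
        self.mpairs = _PairSet(
            self.idx.pairs_in_window(self.p.motor_binding_window), self.idx.n,
            occ_m)
        self.fil_ids = sorted(state.filaments)
        self.sched.add_channel(self.POLY, self._poly_rate())
        self.sched.add_channel(self.DEPOLY, self._depoly_rate())
        self.sched.add_channel(self.LBIND, self._lbind_rate())
        self.sched.add_channel(self.MBIND, self._mbind_rate())
        for lid in sorted(state.linkers):
            self.sched.add_channel(("lu", lid, 0), self._lu_rate(lid))
        for mid in sorted(state.motors):
            self._add_motor_channels(mid)

    # -- propensities --------------------------------------------------
    def _poly_rate(self) -> float:
        if self.state.free_g_actin < 1:
            return 0.0
        return len(self.fil_ids) * self.p.k_poly * self.state.free_g_actin

    def _depoly_eligible(self) -> List[int]:
        return [fid for fid in self.fil_ids
                if sum(self.state.filaments[fid].monomers) > 1]

    def _depoly_rate(self) -> float:
        return len(self._depoly_eligible()) * self.p.k_depoly

    def _lbind_rate(self) -> float:
        return len(self.lpairs) * self.p.chi * self.p.k_on_linker * self.state.free_linker

    def _mbind_rate(self) -> float:
        return len(self.mpairs) * self.p.k_on_motor * self.state.free_motor

    def _lu_rate(self, lid: int) -> float:
        return linker_unbind_rate(linker_tension(self.state, self.state.linkers[lid]),
                                  self.p)

    def _mu_rate(self, mid: int) -> float:
        return motor_unbind_rate(motor_tension(self.state, self.state.motors[mid]),
                                 self.p)

    def _mw_rate(self, mid: int, end: int) -> float:
        m = self.state.motors[mid]
        if m.ends[end][1] <= 0.0:
            return 0.0
        return motor_walk_rate(motor_tension(self.state, m), self.p)

    def _add_motor_channels(self, mid: int) -> None:
        self.sched.add_channel(("mu", mid, 0), self._mu_rate(mid))
        self.sched.add_channel(("mw", mid, 0), self._mw_rate(mid, 0))
        self.sched.add_channel(("mw", mid, 1), self._mw_rate(mid, 1))

    def _remove_entity_channels(self, kind: str, eid: int) -> None:
        if kind == "linker":
            self.sched.remove_channel(("lu", eid, 0))
        else:
            self.sched.remove_channel(("mu", eid, 0))
            self.sched.remove_channel(("mw", eid, 0))
            self.sched.remove_channel(("mw", eid, 1))

    def _pairset(self, kind: str) -> _PairSet:
        return self.lpairs if kind == "linker" else self.mpairs

    def _free_sites(self, kind: str, sites) -> None:
        ps = self._pairset(kind)
        for site in sites:
            g = self.idx.gidx_or_none(site)
            if g is not None:
                ps.free(g)

    def _occupy_sites(self, kind: str, sites) -> None:
        ps = self._pairset(kind)
        for site in sites:
            g = self.idx.gidx_or_none(site)
            if g is not None:
                ps.occupy(g)

    def _refresh_bind_rates(self) -> None:
        self.sched.set_rate(self.LBIND, self._lbind_rate())
        self.sched.set_rate(self.MBIND, self._mbind_rate())

    def _release(self, kind: str, eid: int) -> None:
        table = self.state.linkers if kind == "linker" else self.state.motors
        e = table.get(eid)
        if e is None:
            return
        sites = e.sites
        release_entity(self.state, kind, eid)
        self._remove_entity_channels(kind, eid)
        self._free_sites(kind, sites)
        self._refresh_bind_rates()

    # -- event dispatch --------------------------------------------------
    def _fire(self, key: tuple) -> None:
        st = self.state
        kind = key[0]
        if kind == "poly":
            fid = self.fil_ids[int(st.rng.integers(len(self.fil_ids)))]
            polymerize(st, fid)
            if self.log is not None:
                self.log.append((st.t, "polymerize", fid))
            self.sched.set_rate(self.POLY, self._poly_rate())
            self.sched.set_rate(self.DEPOLY, self._depoly_rate())
        elif kind == "depoly":
            eligible = self._depoly_eligible()
            if eligible:
                fid = eligible[int(st.rng.integers(len(eligible)))]
                released, removed_site = depolymerize(st, fid)
                if self.log is not None:
                    self.log.append((st.t, "depolymerize", fid))
                    for rk, reid, _ in released:
                        self.log.append((st.t, f"{rk}_unbind", reid))
                for rk, reid, sites in released:
                    self._remove_entity_channels(rk, reid)
                    self._free_sites(rk, sites)
                if removed_site is not None:
                    # the deleted bead's site can never rebind this slice
                    self._occupy_sites("linker", (removed_site,))
                    self._occupy_sites("motor", (removed_site,))
                if released or removed_site is not None:
                    self._refresh_bind_rates()
            self.sched.set_rate(self.POLY, self._poly_rate())
            self.sched.set_rate(self.DEPOLY, self._depoly_rate())
        elif kind == "lbind":
            ga, gb = self.lpairs.sample(st.rng)
            site_a, site_b = self.idx.site(ga), self.idx.site(gb)
            lid = bind_pair(st, "linker", site_a, site_b)
            if self.log is not None:
                self.log.append((st.t, "linker_bind", lid))
            self._occupy_sites("linker", (site_a, site_b))
            self.sched.add_channel(("lu", lid, 0), self._lu_rate(lid))
            self._refresh_bind_rates()
        elif kind == "mbind":
            ga, gb = self.mpairs.sample(st.rng)
            site_a, site_b = self.idx.site(ga), self.idx.site(gb)
            mid = bind_pair(st, "motor", site_a, site_b)
            if self.log is not None:
                self.log.append((st.t, "motor_bind", mid))
            self._occupy_sites("motor", (site_a, site_b))
            self._add_motor_channels(mid)
            self._refresh_bind_rates()
        elif kind == "lu":
            if self.log is not None:
                self.log.append((st.t, "linker_unbind", key[1]))
            self._release("linker", key[1])
        elif kind == "mu":
            if self.log is not None:
                self.log.append((st.t, "motor_unbind", key[1]))
            self._release("motor", key[1])
        elif kind == "mw":
            mid, end = key[1], key[2]
            if mid in st.motors:
                motor_walk(st, mid, end)
                if self.log is not None:
                    self.log.append((st.t, "motor_walk", mid))
                self.sched.set_rate(("mu", mid, 0), self._mu_rate(mid))
                self.sched.set_rate(("mw", mid, 0), self._mw_rate(mid, 0))
                self.sched.set_rate(("mw", mid, 1), self._mw_rate(mid, 1))
        else:  # pragma: no cover
            raise RuntimeError(f"unknown channel kind {kind!r}")

    def advance(self, until: float) -> int:
        """Fire events in exact NRM order until the clock reaches ``until``."""
        if until < self.state.t:
            raise ValueError("cannot advance backwards in time")
        n_events = 0
        while True:
            key = self.sched.next_event(until)
            if key is None:
                break
            self.state.t = self.sched.t
            self._fire(key)
            n_events += 1
        self.state.t = until
        return n_events


def nrm_advance(state: SystemState, until: float) -> int:
    """Advance the chemistry to ``until`` with propensities frozen to the
    current geometry; returns the number of events fired."""
    return ChemistryEngine(state).advance(until)
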