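"""System state for the minimal stress fiber.

Filaments are bead--cylinder chains: bead 0 is the plus (barbed) end, held
to a focal-adhesion point by a harmonic spring; the last bead is the
dynamic tip where polymerization and depolymerization occur (the model
swaps the growth dynamics onto the inward-facing end so the two bundles
grow towards each other).  Crosslinkers and motors are harmonic springs
whose endpoints live at arc-length coordinates measured in nm from the
plus end along the rest-length contour; endpoints ride rigidly with their
host beads when the network deforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .params import Parameters

SNAPSHOT_FORMAT_VERSION = 1

__all__ = [
    "Filament",
    "BoundLinker",
    "BoundMotor",
    "FASite",
    "SystemState",
    "validate",
    "save_snapshot",
    "load_snapshot",
    "state_to_dict",
    "state_from_dict",
]


@dataclass
class Filament:
    id: int
    beads: np.ndarray                  # (n_beads, 3) nm
    monomers: List[int]                # per cylinder, len n_beads - 1
    attachment: Optional[int] = None   # FA site id anchoring bead 0, or None

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    def rest_lengths(self, rise: float) -> np.ndarray:
        return np.asarray(self.monomers, dtype=float) * rise

    def contour_length(self, rise: float) -> float:
        return float(sum(self.monomers)) * rise

    def cum_rest(self, rise: float) -> np.ndarray:
        """Cumulative rest-length arc coordinate of each bead (bead 0 -> 0)."""
        out = np.zeros(self.n_beads)
        np.cumsum(self.rest_lengths(rise), out=out[1:])
        return out

    def locate(self, arc: float, rise: float) -> Tuple[int, float]:
        """Map an arc coordinate to (cylinder index, fraction along it)."""
        cum = self.cum_rest(rise)
        total = cum[-1]
        arc = min(max(arc, 0.0), total)
        j = int(np.searchsorted(cum, arc, side="right") - 1)
        j = min(j, self.n_beads - 2)
        rest = cum[j + 1] - cum[j]
        frac = 0.0 if rest <= 0 else (arc - cum[j]) / rest
        return j, min(max(frac, 0.0), 1.0)

    def point_at(self, arc: float, rise: float) -> np.ndarray:
        j, frac = self.locate(arc, rise)
        return (1.0 - frac) * self.beads[j] + frac * self.beads[j + 1]

    @property
    def tip(self) -> np.ndarray:
        """Position of the dynamic (inward-facing) end."""
        return self.beads[-1]


@dataclass
class BoundLinker:
    id: int
    ends: Tuple[Tuple[int, float], Tuple[int, float]]  # ((fil, arc), (fil, arc))
    species: str = "alpha-actinin"
    sites: Tuple[Tuple[int, int], Tuple[int, int]] = ((-1, -1), (-1, -1))


@dataclass
class BoundMotor:
    id: int
    ends: Tuple[Tuple[int, float], Tuple[int, float]]
    species: str = "NMII"
    sites: Tuple[Tuple[int, int], Tuple[int, int]] = ((-1, -1), (-1, -1))


@dataclass
class FASite:
    id: int
    position: np.ndarray               # (3,) nm, fixed except through pulling
    attached: List[int] = field(default_factory=list)  # filament ids


class SystemState:
    """Complete mechanochemical state of the fiber plus the well-mixed pools."""

    def __init__(self, params: Parameters):
        self.params = params
        self.filaments: Dict[int, Filament] = {}
        self.linkers: Dict[int, BoundLinker] = {}
        self.motors: Dict[int, BoundMotor] = {}
        self.fa_sites: List[FASite] = []
        self.free_g_actin: int = params.g_actin_init
        self.free_linker: int = params.n_crosslinker
        self.free_motor: int = params.n_motor
        self.total_actin: int = params.g_actin_init  # free + polymerized
        self.t: float = 0.0
        self.rng: np.random.Generator = np.random.default_rng(params.seed)
        # per-species hinge-site occupancy (alpha-actinin and NMII engage
        # different interfaces, so one site may host one of each)
        self.occupied_linker: Dict[Tuple[int, int], int] = {}
        self.occupied_motor: Dict[Tuple[int, int], int] = {}
        self._next_id: int = 0

    # ------------------------------------------------------------------
    def occupied_sites(self, kind: str) -> Dict[Tuple[int, int], int]:
        return self.occupied_linker if kind == "linker" else self.occupied_motor

    def new_id(self) -> int:
        self._next_id += 1
        return self._next_id - 1

    def polymerized_monomers(self) -> int:
        return sum(sum(f.monomers) for f in self.filaments.values())

    def endpoint_position(self, end: Tuple[int, float]) -> np.ndarray:
        fil_id, arc = end
        return self.filaments[fil_id].point_at(arc, self.params.monomer_rise)

    def spring_length(self, entity) -> float:
        p0 = self.endpoint_position(entity.ends[0])
        p1 = self.endpoint_position(entity.ends[1])
        return float(np.linalg.norm(p1 - p0))

    def hinge_points(self) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
        """All hinge points (beads) as an (N,3) array plus (fil, bead) labels.

        Each hinge point is a potential crosslinker/motor binding site.
        """
        pts, labels = [], []
        for fid in sorted(self.filaments):
            f = self.filaments[fid]
            for b in range(f.n_beads):
                pts.append(f.beads[b])
                labels.append((fid, b))
        if not pts:
            return np.zeros((0, 3)), []
        return np.asarray(pts), labels

    def bundle_filaments(self, site_id: int) -> List[int]:
        return sorted(self.fa_sites[site_id].attached)

    def copy(self) -> "SystemState":
        return state_from_dict(state_to_dict(self))


# ----------------------------------------------------------------------
def validate(state: SystemState) -> List[str]:
    """Check every structural invariant; return human-readable violations."""
    p = state.params
    out: List[str] = []
    for fid, f in state.filaments.items():
        if f.n_beads < 2:
            out.append(f"filament {fid}: fewer than 2 beads")
            continue
        if len(f.monomers) != f.n_beads - 1:
            out.append(f"filament {fid}: monomer list does not match cylinders")
        d = np.linalg.norm(np.diff(f.beads, axis=0), axis=1)
        if np.any(d <= 0) or np.any(d > 1.5 * p.cylinder_rest_length):
            out.append(
                f"filament {fid}: consecutive-bead distance outside "
                f"(0, {1.5 * p.cylinder_rest_length}]"
            )
        if any(m < 0 for m in f.monomers):
            out.append(f"filament {fid}: negative monomer count")
        if f.attachment is not None and fid not in state.fa_sites[f.attachment].attached:
            out.append(f"filament {fid}: attachment not mirrored by FA site")
    for name, table in (("linker", state.linkers), ("motor", state.motors)):
        for eid, e in table.items():
            (f0, a0), (f1, a1) = e.ends
            if f0 == f1:
                out.append(f"{name} {eid}: both endpoints on filament {f0}")
            for fi, ai in e.ends:
                if fi not in state.filaments:
                    out.append(f"{name} {eid}: endpoint on missing filament {fi}")
                else:
                    L = state.filaments[fi].contour_length(p.monomer_rise)
                    if not (0.0 <= ai <= L + 1e-9):
                        out.append(f"{name} {eid}: arc {ai:.2f} outside [0, {L:.2f}]")
            if f0 in state.filaments and f1 in state.filaments:
                if state.spring_length(e) <= 0:
                    out.append(f"{name} {eid}: zero end-to-end length")
    if state.free_linker + len(state.linkers) != p.n_crosslinker:
        out.append(
            "crosslinker conservation violated: "
            f"{state.free_linker} free + {len(state.linkers)} bound != {p.n_crosslinker}"
        )
    if state.free_motor + len(state.motors) != p.n_motor:
        out.append(
            "motor conservation violated: "
            f"{state.free_motor} free + {len(state.motors)} bound != {p.n_motor}"
        )
    if state.free_g_actin + state.polymerized_monomers() != state.total_actin:
        out.append(
            "actin mass conservation violated: "
            f"{state.free_g_actin} free + {state.polymerized_monomers()} polymerized "
            f"!= {state.total_actin}"
        )
    if state.free_g_actin < 0:
        out.append("negative free G-actin pool")
    return out


# ----------------------------------------------------------------------
# Snapshot serialization (versioned plain-text JSON).

def state_to_dict(state: SystemState) -> dict:
    return {
        "format_version": SNAPSHOT_FORMAT_VERSION,
        "params": state.params.to_dict(),
        "t": state.t,
        "free_g_actin": state.free_g_actin,
        "free_linker": state.free_linker,
        "free_motor": state.free_motor,
        "total_actin": state.total_actin,
        "next_id": state._next_id,
        "rng_state": state.rng.bit_generator.state,
        "filaments": [
            {
                "id": f.id,
                "beads": f.beads.tolist(),
                "monomers": list(map(int, f.monomers)),
                "attachment": f.attachment,
            }
            for f in (state.filaments[k] for k in sorted(state.filaments))
        ],
        "linkers": [
            {"id": e.id, "ends": [list(e.ends[0]), list(e.ends[1])],
             "sites": [list(e.sites[0]), list(e.sites[1])], "species": e.species}
            for e in (state.linkers[k] for k in sorted(state.linkers))
        ],
        "motors": [
            {"id": e.id, "ends": [list(e.ends[0]), list(e.ends[1])],
             "sites": [list(e.sites[0]), list(e.sites[1])], "species": e.species}
            for e in (state.motors[k] for k in sorted(state.motors))
        ],
        "fa_sites": [
            {"id": s.id, "position": s.position.tolist(), "attached": list(s.attached)}
            for s in state.fa_sites
        ],
        "occupied_linker": [[list(site), eid] for site, eid
                            in sorted(state.occupied_linker.items())],
        "occupied_motor": [[list(site), eid] for site, eid
                           in sorted(state.occupied_motor.items())],
    }


def state_from_dict(d: dict) -> SystemState:
    if d.get("format_version") != SNAPSHOT_FORMAT_VERSION:
        raise ValueError(
            f"snapshot format version {d.get('format_version')!r} not supported "
            f"(expected {SNAPSHOT_FORMAT_VERSION})"
        )
    params = Parameters.from_dict(d["params"])
    state = SystemState(params)
    state.t = float(d["t"])
    state.free_g_actin = int(d["free_g_actin"])
    state.free_linker = int(d["free_linker"])
    state.free_motor = int(d["free_motor"])
    state.total_actin = int(d["total_actin"])
    state._next_id = int(d["next_id"])
    state.rng.bit_generator.state = d["rng_state"]
    for fd in d["filaments"]:
        f = Filament(
            id=int(fd["id"]),
            beads=np.asarray(fd["beads"], dtype=float),
            monomers=list(map(int, fd["monomers"])),
            attachment=fd["attachment"],
        )
        state.filaments[f.id] = f
    for ld in d["linkers"]:
        e = BoundLinker(
            id=int(ld["id"]),
            ends=(tuple(ld["ends"][0]), tuple(ld["ends"][1])),
            sites=(tuple(ld["sites"][0]), tuple(ld["sites"][1])),
            species=ld["species"],
        )
        state.linkers[e.id] = e
    for md in d["motors"]:
        e = BoundMotor(
            id=int(md["id"]),
            ends=(tuple(md["ends"][0]), tuple(md["ends"][1])),
            sites=(tuple(md["sites"][0]), tuple(md["sites"][1])),
            species=md["species"],
        )
        state.motors[e.id] = e
    state.fa_sites = [
        FASite(id=int(sd["id"]), position=np.asarray(sd["position"], dtype=float),
               attached=list(map(int, sd["attached"])))
        for sd in d["fa_sites"]
    ]
    state.occupied_linker = {
        tuple(site): int(eid) for site, eid in d.get("occupied_linker", [])
    }
    state.occupied_motor = {
        tuple(site): int(eid) for site, eid in d.get("occupied_motor", [])
    }
    return state


def save_snapshot(state: SystemState, path) -> None:
    with open(path, "w") as fh:
        json.dump(state_to_dict(state), fh)


def load_snapshot(path) -> SystemState:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as err:
            raise ValueError(f"corrupt or truncated snapshot file {path}: {err}")
    return state_from_dict(d)
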