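"""Construction of the minimal stress fiber, the coupled
chemistry--mechanics loop, and the tensile-pulling protocol.

The fiber is two antiparallel bundles: each focal-adhesion (FA) point
anchors the plus ends of ``n_filaments_per_bundle`` filaments whose
dynamic (growing) ends face the opposite FA.  Growth from the shared
G-actin pool makes the bundles interdigitate; motors walking towards the
plus ends then contract the fiber against the FA springs.

``run`` alternates exact stochastic chemistry over ``sync_dt`` with
conjugate-gradient mechanical relaxation, sampling an observable frame
every ``sample_dt``.  ``apply_pull`` displaces one FA site outward in
small consecutive steps (minimizing after each) to emulate a tensile
stretching stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .chemistry import ChemistryEngine
from .geometry import anchor_axial_offsets, hex_lattice_points
from .mechanics import minimize
from .observables import measure_frame
from .params import Parameters
from .state import FASite, Filament, SystemState

__all__ = ["PullSpec", "Trajectory", "build_stress_fiber", "run", "apply_pull"]


@dataclass
class PullSpec:
    d_pull: float                # nm, total outward displacement of one FA site
    n_steps: int = 20
    duration: float = 1.0        # s of simulated time for the whole pull
    t_pull: Optional[float] = None  # clock time at which pulling starts

    def __post_init__(self):
        if self.d_pull < 0:
            raise ValueError("d_pull must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class Trajectory:
    params: Parameters
    seed: int
    rows: List[Dict[str, float]] = field(default_factory=list)
    events: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def series(self, field_name: str) -> np.ndarray:
        return self.to_dataframe()[field_name].to_numpy()

    @property
    def times(self) -> np.ndarray:
        return self.series("t")


# ----------------------------------------------------------------------
def build_stress_fiber(params: Parameters) -> SystemState:
    """Initial fiber: two anchored bundles of single-cylinder filaments.

    FA sites sit on the box long (z) axis, symmetric about the centre;
    anchors occupy a hexagonal lattice on the FA attachment sphere; every
    filament starts as one full cylinder (40 monomers) debited from the
    G-actin pool, minus end pointing at the other site.
    """
    params.validate()
    state = SystemState(params)
    bx, by, bz = params.box
    centre = np.array([bx / 2.0, by / 2.0, bz / 2.0])
    half = params.fa_separation / 2.0
    fa_z = [centre[2] - half, centre[2] + half]
    n = params.n_filaments_per_bundle
    lat = hex_lattice_points(n, params.anchor_lattice_spacing)
    axial = anchor_axial_offsets(n, params.anchor_lattice_spacing,
                                 params.fa_rest_length)
    init_monomers = params.init_cylinders_per_filament * params.monomers_per_cylinder
    needed = 2 * n * init_monomers
    if needed > state.free_g_actin:
        raise ValueError("G-actin pool too small to seed the filaments")

    for side in (0, 1):
        fa_pos = np.array([centre[0], centre[1], fa_z[side]])
        site = FASite(id=side, position=fa_pos)
        state.fa_sites.append(site)
        direction = 1.0 if side == 0 else -1.0     # growth towards the centre
        for k in range(n):
            anchor = fa_pos + np.array([lat[k, 0], lat[k, 1],
                                        direction * axial[k]])
            beads = [anchor]
            monomers = []
            for _ in range(params.init_cylinders_per_filament):
                beads.append(beads[-1] + np.array(
                    [0.0, 0.0, direction * params.cylinder_rest_length]))
                monomers.append(params.monomers_per_cylinder)
            fid = state.new_id()
            state.filaments[fid] = Filament(
                id=fid, beads=np.asarray(beads, dtype=float),
                monomers=monomers, attachment=side,
            )
            site.attached.append(fid)
    state.free_g_actin -= needed
    return state


# ----------------------------------------------------------------------
def run(
    state: SystemState,
    t_end: float,
    sync_dt: Optional[float] = None,
    sample_dt: Optional[float] = None,
    trajectory: Optional[Trajectory] = None,
) -> Trajectory:
    """Advance the coupled chemistry--mechanics loop to ``t_end``.

    Chemistry propensities are frozen over each ``sync_dt`` slice, then the
    network is relaxed.  A frame is recorded at t = 0 (or the first call)
    and every ``sample_dt`` thereafter.  Passing an existing trajectory
    continues it (used by the pulling protocol).
    """
    p = state.params
    sync = p.sync_dt if sync_dt is None else sync_dt
    sample = p.sample_dt if sample_dt is None else sample_dt
    if t_end < state.t:
        raise ValueError("t_end is before the current clock")
    traj = trajectory if trajectory is not None else Trajectory(p, p.seed)
    if not traj.rows:
        minimize(state)
        traj.rows.append(measure_frame(state).to_row())
    next_sample = (np.floor(state.t / sample) + 1) * sample
    while state.t < t_end - 1e-12:
        t_next = min(state.t + sync, t_end)
        engine = ChemistryEngine(state)
        traj.events += engine.advance(t_next)
        minimize(state)
        while next_sample <= state.t + 1e-9:
            traj.rows.append(measure_frame(state).to_row())
            next_sample += sample
    return traj


def apply_pull(
    state: SystemState,
    spec: PullSpec,
    trajectory: Optional[Trajectory] = None,
) -> Trajectory:
    """Move FA site 1 outward along the fiber axis by ``d_pull``.

    The displacement is broken into ``n_steps`` consecutive sub-steps over
    ``spec.duration`` seconds of simulated time; after each sub-step the
    chemistry advances by duration/n_steps and the energy is re-minimized.
    Records a frame immediately before and immediately after the pull.
    """
    p = state.params
    axis = state.fa_sites[1].position - state.fa_sites[0].position
    axis = axis / np.linalg.norm(axis)
    target = state.fa_sites[1].position + spec.d_pull * axis
    if not (0.0 <= target[2] <= p.box[2]):
        raise ValueError("pull would move the FA site outside the box")
    traj = trajectory if trajectory is not None else Trajectory(p, p.seed)
    minimize(state)
    traj.rows.append(measure_frame(state).to_row())
    step = spec.d_pull / spec.n_steps
    dt = spec.duration / spec.n_steps
    for _ in range(spec.n_steps):
        state.fa_sites[1].position = state.fa_sites[1].position + step * axis
        engine = ChemistryEngine(state)
        traj.events += engine.advance(state.t + dt)
        minimize(state)
    traj.rows.append(measure_frame(state).to_row())
    return traj
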