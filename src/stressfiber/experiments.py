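"""Reusable measurement protocols built on the simulator.

These functions encapsulate the standard numerical experiments: unloaded
crosslinker lifetimes, the default development run with its plateau
statistics, the tensile-pull response, and reduced-scale parameter
sweeps.  They are consumed both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chemistry import ChemistryEngine
from .observables import binding_site_rdf, overlap_distance
from .params import Parameters, default_parameters, desk_scale_parameters
from .protocol import PullSpec, Trajectory, apply_pull, build_stress_fiber, run
from .state import SystemState
from .synthetic import generate_static_bundle

__all__ = [
    "linker_lifetime_experiment",
    "default_run",
    "plateau_stats",
    "state_nearest_overlap",
    "state_nearest_plateau",
    "steady_state_rdf_argmax",
    "pull_response",
    "sweep_steady_state",
]


def linker_lifetime_experiment(
    chi: float,
    n_events: int = 10_000,
    seed: int = 0,
    n_filaments: int = 7,
    n_beads: int = 40,
) -> Tuple[float, float, int]:
    """Mean unloaded crosslinker bound lifetime from the stochastic engine.

    Crosslinkers bind and unbind on a static hexagonal bundle whose
    lattice spacing equals the linker rest length, so every bond carries
    zero force and the unbinding propensity is exactly chi * k_off.
    Polymerization, depolymerization and motor activity are switched off.
    The run extends well past ``n_events`` completed unbind events and at
    least 200 mean lifetimes, keeping the right-censoring bias of
    completed-lifetime sampling far below the standard error.

    Returns (mean lifetime, standard error, number of events used).
    """
    p = default_parameters().replace(
        chi=chi, seed=seed,
        k_depoly=1e-12, k_on_motor=1e-300, k_off_motor=1e-300,
    )
    state = generate_static_bundle(
        spacing=p.linker_rest_length, n_filaments=n_filaments,
        n_beads=n_beads, params=p, seed=seed,
    )
    state.free_g_actin = 0          # no polymerization from an empty pool
    state.total_actin = state.polymerized_monomers()

    mean_expected = 1.0 / (chi * p.k_off_linker)
    slice_t = 50.0 * mean_expected
    bind_times: Dict[int, float] = {}
    lifetimes: List[float] = []
    t_min = 200.0 * mean_expected
    while len(lifetimes) < n_events or state.t < t_min:
        engine = ChemistryEngine(state, record_events=True)
        engine.advance(state.t + slice_t)
        for t, kind, eid in engine.log:
            if kind == "linker_bind":
                bind_times[eid] = t
            elif kind == "linker_unbind" and eid in bind_times:
                lifetimes.append(t - bind_times.pop(eid))
    arr = np.asarray(lifetimes)
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(len(arr))), len(arr)


# ----------------------------------------------------------------------
@dataclass
class RunResult:
    trajectory: Trajectory
    state: SystemState                      # final state
    snapshots: Dict[float, SystemState]     # requested intermediate copies


def default_run(
    seed: int = 0,
    t_end: float = 600.0,
    sync_dt: float = 0.5,
    params: Optional[Parameters] = None,
    snapshot_times: Sequence[float] = (),
) -> RunResult:
    """Build the default fiber and run it to ``t_end``.

    ``sync_dt`` defaults to a coarse 0.5 s coupling interval -- the
    production resolution used for the desk-scale reproductions (see the
    methods note on the choice).
    """
    p = (params if params is not None else default_parameters()).replace(
        seed=seed, sync_dt=sync_dt)
    state = build_stress_fiber(p)
    traj: Optional[Trajectory] = None
    snaps: Dict[float, SystemState] = {}
    marks = sorted(set(float(t) for t in snapshot_times if t <= t_end))
    for mark in marks + ([t_end] if t_end not in marks else []):
        traj = run(state, mark, trajectory=traj)
        if mark in marks:
            snaps[mark] = state.copy()
    return RunResult(trajectory=traj, state=state, snapshots=snaps)


def plateau_stats(traj: Trajectory, field: str = "d_overlap",
                  window: Tuple[float, float] = (400.0, 600.0)
                  ) -> Tuple[float, float]:
    """Mean and std of a trajectory field over a time window."""
    df = traj.to_dataframe()
    sel = df[(df["t"] >= window[0]) & (df["t"] <= window[1])]
    if not len(sel):
        raise ValueError("window contains no samples")
    return float(sel[field].mean()), float(sel[field].std())


def steady_state_rdf_argmax(states: Sequence[SystemState]) -> float:
    """Arg-max bin centre of the binding-site radial density averaged over
    steady-state snapshots."""
    if not states:
        raise ValueError("need at least one snapshot")
    rdfs = [binding_site_rdf(s) for s in states]
    mean_P = np.mean([r.values for r in rdfs], axis=0)
    centers = rdfs[0].bin_centers
    return float(centers[int(np.argmax(mean_P))])


def state_nearest_overlap(states: Sequence[SystemState],
                          target: float) -> SystemState:
    """The stored state whose bundle overlap is closest to ``target``.

    The tensile-pulling protocol starts from a fiber equilibrated at a
    stated overlap; replicate-to-replicate tip dispersion and the slow
    ratchet creep scatter the achieved plateaus, so the pull substrate is
    picked by its overlap, not by wall-clock time."""
    if not states:
        raise ValueError("no candidate states")
    return min(states, key=lambda s: abs(overlap_distance(s)[0] - target))


def state_nearest_plateau(run_result: RunResult,
                          window: Tuple[float, float] = (400.0, 600.0)
                          ) -> SystemState:
    """The stored state whose overlap is closest to the run's own plateau."""
    target, _ = plateau_stats(run_result.trajectory, "d_overlap", window)
    return state_nearest_overlap(
        list(run_result.snapshots.values()) + [run_result.state], target)


def pull_response(
    state: SystemState,
    d_pull: float = 100.0,
    relax: float = 0.0,
    n_steps: int = 20,
    duration: float = 1.0,
) -> Tuple[Trajectory, float, float]:
    """Apply a tensile pull and optionally follow the relaxation.

    Returns (trajectory, overlap just before the pull, overlap in the
    first frame after the pull).  The trajectory's first two rows are the
    pre/post frames; the relaxation follows at the sampling cadence.
    """
    spec = PullSpec(d_pull=d_pull, n_steps=n_steps, duration=duration,
                    t_pull=state.t)
    traj = apply_pull(state, spec)
    ov_before = traj.rows[0]["d_overlap"]
    ov_after = traj.rows[1]["d_overlap"]
    if relax > 0:
        run(state, state.t + relax, trajectory=traj)
    return traj, float(ov_before), float(ov_after)


def sweep_steady_state(
    vary: str,
    values: Sequence,
    seeds: Sequence[int],
    n_filaments_per_bundle: int = 6,
    t_end: float = 240.0,
    window: Tuple[float, float] = (160.0, 240.0),
    target_overlap: float = 450.0,
) -> Dict:
    """Reduced-scale parameter sweep of the steady-state contractility.

    Returns {value: {"e_ss": [...], "cv": [...]}} with one entry per seed;
    the reduced system keeps the default geometry but scales protein
    counts with the filament number (see ``desk_scale_parameters``).
    """
    out: Dict = {}
    for v in values:
        e_list, cv_list = [], []
        for s in seeds:
            p = desk_scale_parameters(
                n_filaments_per_bundle=n_filaments_per_bundle, seed=s,
                t_measure=0.5 * (window[0] + window[1]),
                target_overlap=target_overlap,
            ).replace(**{vary: v})
            state = build_stress_fiber(p)
            traj = run(state, t_end)
            mean, std = plateau_stats(traj, "E_FA", window)
            e_list.append(mean)
            cv_list.append(std / mean if mean > 0 else float("nan"))
        out[v] = {"e_ss": e_list, "cv": cv_list}
    return out
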