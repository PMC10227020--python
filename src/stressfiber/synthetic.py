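"""Surrogate data with known ground truth.

Two generators make the analysis and observable stages testable without
running the simulator:

* :func:`generate_energy_trace` -- a development-ramp / plateau / optional
  pull-and-relax energy time series with Ornstein--Uhlenbeck (OU)
  fluctuations.  The OU process matches the correlated fluctuations seen
  on real steady-state traces while having an exactly known stationary
  law (mean 0, std sigma, correlation time theta).
* :func:`generate_static_bundle` -- parallel unstressed filaments on a
  hexagonal lattice, for exercising the radial density, binding-candidate
  search and mechanics on known geometry.

Both are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .geometry import hex_lattice_points
from .params import Parameters, default_parameters
from .state import Filament, SystemState

__all__ = ["SurrogateSpec", "generate_energy_trace", "generate_observable_table",
           "generate_static_bundle"]


@dataclass
class SurrogateSpec:
    mu: float = 4000.0          # plateau mean
    sigma: float = 200.0        # OU stationary std on the plateau
    theta: float = 5.0          # OU correlation time, s
    t_ramp_end: float = 200.0   # development ramp reaches mu here
    t_pull: Optional[float] = None  # optional step time, s
    step: float = 2000.0        # energy jump at the pull
    tau_true: float = 15.0      # relaxation time back to mu, s
    duration: float = 600.0     # s
    sample_dt: float = 1.0      # s
    seed: int = 0

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.tau_true <= 0 or self.theta <= 0:
            raise ValueError("tau_true and theta must be > 0")
        if not 0 <= self.t_ramp_end <= self.duration:
            raise ValueError("need 0 <= t_ramp_end <= duration")
        if self.t_pull is not None and not (
                self.t_ramp_end <= self.t_pull < self.duration):
            raise ValueError("need t_ramp_end <= t_pull < duration")


def _mean_path(spec: SurrogateSpec, t: np.ndarray) -> np.ndarray:
    if spec.t_ramp_end > 0:
        m = spec.mu * np.minimum(t / spec.t_ramp_end, 1.0)
    else:
        m = np.full_like(t, spec.mu)
    if spec.t_pull is not None:
        after = t >= spec.t_pull
        m = np.where(
            after,
            spec.mu + spec.step * np.exp(-(t - spec.t_pull) / spec.tau_true),
            m,
        )
    return m


def generate_energy_trace(spec: SurrogateSpec):
    """Return (times, values) for one surrogate trajectory.

    values = deterministic mean path + stationary OU noise sampled exactly
    at the grid points (x_{k+1} = a x_k + sigma sqrt(1-a^2) xi with
    a = exp(-dt/theta) and x_0 ~ N(0, sigma)).
    """
    spec.validate()
    t = np.arange(0.0, spec.duration + 0.5 * spec.sample_dt, spec.sample_dt)
    m = _mean_path(spec, t)
    if spec.sigma == 0:
        return t, m
    rng = np.random.default_rng(spec.seed)
    a = np.exp(-spec.sample_dt / spec.theta)
    x = np.empty(len(t))
    x[0] = spec.sigma * rng.standard_normal()
    innov = spec.sigma * np.sqrt(1.0 - a * a) * rng.standard_normal(len(t) - 1)
    for k in range(1, len(t)):
        x[k] = a * x[k - 1] + innov[k - 1]
    return t, m + x


def generate_observable_table(spec: SurrogateSpec) -> pd.DataFrame:
    """Surrogate trajectory in the same table schema as the simulator output
    (only the energy column is meaningful; composition columns are zero)."""
    t, y = generate_energy_trace(spec)
    df = pd.DataFrame({"t": t, "E_FA": y})
    for col in ("F_FA", "n_bound_linkers", "n_bound_motors", "d_overlap"):
        df[col] = 0.0
    return df


# ----------------------------------------------------------------------
def generate_static_bundle(
    spacing: float,
    n_filaments: int,
    n_beads: int,
    params: Optional[Parameters] = None,
    seed: int = 0,
) -> SystemState:
    """Parallel, unstressed filaments on a hexagonal lattice (no FA sites,
    no bound species) for geometry-controlled tests."""
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if n_filaments < 1 or n_beads < 2:
        raise ValueError("need at least 1 filament with 2 beads")
    p = params if params is not None else default_parameters()
    p = p.replace(seed=seed)
    state = SystemState(p)
    lat = hex_lattice_points(n_filaments, spacing)
    z0 = p.box[2] / 2.0 - (n_beads - 1) * p.cylinder_rest_length / 2.0
    centre = np.array([p.box[0] / 2.0, p.box[1] / 2.0, 0.0])
    for k in range(n_filaments):
        beads = np.array([
            [centre[0] + lat[k, 0], centre[1] + lat[k, 1],
             z0 + b * p.cylinder_rest_length]
            for b in range(n_beads)
        ])
        fid = state.new_id()
        state.filaments[fid] = Filament(
            id=fid, beads=beads,
            monomers=[p.monomers_per_cylinder] * (n_beads - 1),
            attachment=None,
        )
    # synthetic states carry their own mass ledger
    state.total_actin = state.free_g_actin + state.polymerized_monomers()
    return state
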