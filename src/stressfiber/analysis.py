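"""Ensemble statistics: steady-state detection, fluctuation measures, and
log-space relaxation fits.

The fitting stage follows the Model/Results convention: construct a model
from data, call ``fit()``, and read estimates, uncertainties and a
``summary()`` table off the returned results object.

Steady-state detection minimizes, over candidate onset times ``t0``, the
expected squared error of the window estimator ``q_hat_[t0,T]`` (the
sample mean over ``[t0, T]``) against a reference steady-state value
``<q>`` computed from all samples after a late reference time (default
400 s).  Starting the window too early biases the estimator (development
samples contaminate it); starting too late inflates its variance -- the
minimizer balances the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SteadyStateResult",
    "DecayFitResults",
    "PowerLawResults",
    "detect_steady_state",
    "steady_state_cv",
    "ExponentialDecayModel",
    "PowerLawModel",
    "fit_exponential_decay",
    "fit_power_law",
    "ensemble_average",
]


@dataclass
class SteadyStateResult:
    t0: float                 # onset time of the steady state
    mean: float               # ensemble-and-time mean over [t0, T]
    cv: float                 # std/mean over the same window
    n_samples: int
    delta2: float             # minimized expected squared estimator error

    def summary(self) -> str:
        return (
            "Steady-state detection\n"
            f"  t0        = {self.t0:.1f} s\n"
            f"  mean      = {self.mean:.4g}\n"
            f"  CV        = {self.cv:.4f}\n"
            f"  n_samples = {self.n_samples}\n"
        )


def _as_ensemble(series) -> np.ndarray:
    q = np.asarray(series, dtype=float)
    if q.ndim == 1:
        q = q[None, :]
    if q.ndim != 2:
        raise ValueError("series must be 1-D or (replicates, time)")
    return q


def detect_steady_state(
    times: Sequence[float],
    series,
    reference_window_start: float = 400.0,
    literal_prefactor: bool = False,
) -> SteadyStateResult:
    """Estimate the steady-state onset t0 for an ensemble of trajectories.

    ``series`` is (n_replicates, n_times) on a common grid ``times``.  The
    window estimator is the sample mean over [t0, T]; with
    ``literal_prefactor=True`` the sum is divided by the full series length
    T instead (the biased book form, kept for comparison).
    """
    t = np.asarray(times, dtype=float)
    q = _as_ensemble(series)
    if q.shape[1] != len(t):
        raise ValueError("series and times have mismatched lengths")
    ref_mask = t >= reference_window_start
    if not np.any(ref_mask):
        raise ValueError("series shorter than the reference window")
    qbar = float(q[:, ref_mask].mean())

    # suffix means per replicate for every candidate t0 (vectorized)
    T = q.shape[1]
    csum = np.cumsum(q[:, ::-1], axis=1)[:, ::-1]    # csum[:, i] = sum_{j>=i}
    counts = np.arange(T, 0, -1)
    denom = float(T) if literal_prefactor else counts
    qhat = csum / denom
    delta2 = np.mean((qhat - qbar) ** 2, axis=0)
    i0 = int(np.argmin(delta2))
    window = q[:, i0:]
    mean = float(window.mean())
    cv = float(window.std() / mean) if mean != 0 else float("inf")
    return SteadyStateResult(
        t0=float(t[i0]), mean=mean, cv=cv,
        n_samples=int(window.size), delta2=float(delta2[i0]),
    )


def steady_state_cv(series, t0: float, times: Optional[Sequence[float]] = None
                    ) -> float:
    """Coefficient of variation std/mean of the samples at t >= t0."""
    q = np.asarray(series, dtype=float)
    t = np.arange(len(q), dtype=float) if times is None else np.asarray(times, float)
    if not (t[0] <= t0 <= t[-1]):
        raise ValueError("t0 outside the series range")
    window = q[t >= t0]
    mean = window.mean()
    if mean <= 0:
        raise ValueError("steady-state mean must be positive for a CV")
    return float(window.std() / mean)


# ----------------------------------------------------------------------
@dataclass
class DecayFitResults:
    e_peak: float
    e_ss: float
    tau: float                 # s
    tau_ci95: Tuple[float, float]
    rmse: float                # in the units of the series
    slope: float
    intercept: float
    n_obs: int

    def predict(self, t_after_pull: np.ndarray) -> np.ndarray:
        return self.e_ss + (self.e_peak - self.e_ss) * np.exp(
            -np.asarray(t_after_pull, float) / self.tau)

    def summary(self) -> str:
        lo, hi = self.tau_ci95
        return (
            "Exponential relaxation fit (log-space linear regression)\n"
            f"  E_peak = {self.e_peak:.4g}\n"
            f"  E_SS   = {self.e_ss:.4g}\n"
            f"  tau    = {self.tau:.3g} s  (95% CI {lo:.3g} -- {hi:.3g})\n"
            f"  RMSE   = {self.rmse:.4g}\n"
            f"  n      = {self.n_obs}\n"
        )


class ExponentialDecayModel:
    """Post-pull relaxation E(t) = E_SS + (E_peak - E_SS) exp(-t/tau).

    Fit by linear regression of ln(E - E_SS) against time after the pull;
    ``e_ss`` is the known (matched-ensemble or tail) steady-state level.
    """

    def __init__(self, times, values, t_pull: float = 0.0, e_ss: float = 0.0):
        self.t = np.asarray(times, dtype=float)
        self.y = np.asarray(values, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("times and values must have the same shape")
        self.t_pull = float(t_pull)
        self.e_ss = float(e_ss)

    def fit(self) -> DecayFitResults:
        mask = self.t >= self.t_pull
        t = self.t[mask] - self.t_pull
        y = self.y[mask]
        resid = y - self.e_ss
        nonpos = np.nonzero(resid <= 0)[0]
        if len(nonpos):
            cut = int(nonpos[0])
            warnings.warn(
                "non-positive residuals in the fit window; truncating at "
                f"t = {t[cut]:.1f} s after the pull", RuntimeWarning)
            t, y, resid = t[:cut], y[:cut], resid[:cut]
        if len(t) < 5:
            raise ValueError("fewer than 5 usable points for the decay fit")
        reg = sps.linregress(t, np.log(resid))
        if reg.slope >= 0:
            raise ValueError("series does not decay on the fit window")
        tau = -1.0 / reg.slope
        e_peak = self.e_ss + float(np.exp(reg.intercept))
        tcrit = sps.t.ppf(0.975, len(t) - 2)
        slo = reg.slope - tcrit * reg.stderr
        shi = reg.slope + tcrit * reg.stderr
        ci = sorted(
            -1.0 / s if s < 0 else float("inf") for s in (slo, shi))
        pred = self.e_ss + (e_peak - self.e_ss) * np.exp(-t / tau)
        rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
        return DecayFitResults(
            e_peak=e_peak, e_ss=self.e_ss, tau=float(tau),
            tau_ci95=(float(ci[0]), float(ci[1])), rmse=rmse,
            slope=float(reg.slope), intercept=float(reg.intercept),
            n_obs=int(len(t)),
        )


def fit_exponential_decay(times, values, t_pull: float, e_ss: float
                          ) -> DecayFitResults:
    return ExponentialDecayModel(times, values, t_pull, e_ss).fit()


# ----------------------------------------------------------------------
@dataclass
class PowerLawResults:
    exponent: float
    prefactor: float
    rmse: float                # log-space RMSE
    exponent_ci95: Tuple[float, float]
    n_obs: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.prefactor * np.asarray(x, float) ** self.exponent

    def summary(self) -> str:
        lo, hi = self.exponent_ci95
        return (
            "Power-law fit y = A x^b (log-space linear regression)\n"
            f"  b (exponent) = {self.exponent:.4g}  (95% CI {lo:.3g} -- {hi:.3g})\n"
            f"  A (prefactor) = {self.prefactor:.4g}\n"
            f"  RMSE (log space) = {self.rmse:.4g}\n"
            f"  n = {self.n_obs}\n"
        )


class PowerLawModel:
    """y = A x^b fitted by least squares on (ln x, ln y)."""

    def __init__(self, x, y):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if np.any(self.x <= 0) or np.any(self.y <= 0):
            raise ValueError("power-law fitting requires strictly positive data")
        if len(self.x) < 3:
            raise ValueError("need at least 3 points")
        if np.ptp(self.x) == 0:
            raise ValueError("degenerate fit: all x identical")

    def fit(self) -> PowerLawResults:
        lx, ly = np.log(self.x), np.log(self.y)
        reg = sps.linregress(lx, ly)
        pred = reg.intercept + reg.slope * lx
        rmse = float(np.sqrt(np.mean((pred - ly) ** 2)))
        tcrit = sps.t.ppf(0.975, len(lx) - 2) if len(lx) > 2 else float("nan")
        ci = (reg.slope - tcrit * reg.stderr, reg.slope + tcrit * reg.stderr)
        return PowerLawResults(
            exponent=float(reg.slope), prefactor=float(np.exp(reg.intercept)),
            rmse=rmse, exponent_ci95=(float(ci[0]), float(ci[1])),
            n_obs=int(len(lx)),
        )


def fit_power_law(x, y) -> Tuple[float, float, float]:
    res = PowerLawModel(x, y).fit()
    return res.exponent, res.prefactor, res.rmse


# ----------------------------------------------------------------------
def ensemble_average(trajectories, field: str) -> pd.DataFrame:
    """Pointwise ensemble mean with 25th/75th percentile bands.

    ``trajectories`` is a sequence of objects exposing ``to_dataframe()``
    (or DataFrames) sharing a common time grid.  Percentiles use the
    linear-interpolation convention.
    """
    dfs = [tr.to_dataframe() if hasattr(tr, "to_dataframe") else tr
           for tr in trajectories]
    if not dfs:
        raise ValueError("no trajectories given")
    t0 = dfs[0]["t"].to_numpy()
    for df in dfs[1:]:
        if len(df) != len(dfs[0]) or not np.allclose(df["t"].to_numpy(), t0):
            raise ValueError("trajectories are not on a common time grid")
    stack = np.stack([df[field].to_numpy(dtype=float) for df in dfs])
    return pd.DataFrame({
        "t": t0,
        "mean": stack.mean(axis=0),
        "p25": np.percentile(stack, 25, axis=0),
        "p75": np.percentile(stack, 75, axis=0),
    })
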