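"""Trajectory integration, data comparison and perturbation envelopes."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.stats import qmc

from . import ode
from .data import MouseTimeSeries, NormalizationScales
from .parameters import PARAM_NAMES, ParameterSet

__all__ = ["Trajectory", "integrate", "compare_to_data",
           "perturbation_envelope", "PerturbationEnvelope"]

DEFAULT_HORIZON = 126.0  # days (18 weeks), matching the sensitivity horizon


@dataclass(frozen=True)
class Trajectory:
    """Nondimensional solution on a time grid, with solver metadata."""

    times: np.ndarray
    states: np.ndarray            # (n_times, 15)
    scales: NormalizationScales | None = None
    method: str = "LSODA"
    rtol: float = 1e-8
    atol: float = 1e-10

    def component(self, name: str, frame: str = "nondimensional") -> np.ndarray:
        j = ode.VAR_NAMES.index(name)
        col = self.states[:, j]
        if frame == "dimensional":
            if self.scales is None:
                raise ValueError("no scales attached for redimensionalization")
            col = col * self.scales.values[j]
        return col

    def at(self, day: float) -> np.ndarray:
        """Nondimensional state at ``day``, linearly interpolated."""
        if day < self.times[0] or day > self.times[-1]:
            raise ValueError(f"day {day} outside trajectory range")
        return np.array([np.interp(day, self.times, self.states[:, j])
                         for j in range(ode.N_VARS)])

    def to_dataframe(self, frame: str = "nondimensional") -> pd.DataFrame:
        states = self.states
        if frame == "dimensional":
            if self.scales is None:
                raise ValueError("no scales attached")
            states = states * self.scales.values
        recs = [
            {"day": float(t), "variable": v, "value": float(states[i, j]),
             "frame": frame}
            for i, t in enumerate(self.times)
            for j, v in enumerate(ode.VAR_NAMES)
        ]
        return pd.DataFrame(recs)


def integrate(params: ParameterSet, init, horizon: float = DEFAULT_HORIZON,
              grid=None, *, scales: NormalizationScales | None = None,
              method: str = "LSODA", rtol: float = 1e-8,
              atol: float = 1e-10) -> Trajectory:
    """Integrate the nondimensional system from a nonnegative state.

    The default output grid is daily steps on ``[0, horizon]``.  The
    solver uses the analytic state Jacobian; accuracy is controlled by
    ``rtol``/``atol`` and the first output state is the initial
    condition exactly.
    """
    x0 = np.asarray(init, dtype=float)
    if x0.shape != (ode.N_VARS,):
        raise ValueError(f"initial state must have {ode.N_VARS} components")
    if np.any(x0 < 0) or not np.all(np.isfinite(x0)):
        raise ValueError("initial state must be finite and nonnegative")
    if grid is None:
        grid = np.arange(0.0, float(horizon) + 0.5, 1.0)
    grid = np.asarray(grid, dtype=float)
    theta = params.values
    cst = params.constants

    def f(t, x):
        return ode._rhs(x, theta, cst)

    def jac(t, x):
        return ode.jacobian_state(np.clip(x, 0.0, None), theta, cst,
                                  validate=False)

    options = {"jac": jac} if method in ("LSODA", "BDF", "Radau") else {}
    sol = solve_ivp(f, (grid[0], grid[-1]), x0, t_eval=grid, method=method,
                    rtol=rtol, atol=atol, **options)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed at t={sol.t[-1] if sol.t.size else grid[0]}: "
                           f"{sol.message}")
    states = sol.y.T.copy()
    states[0] = x0
    # nonnegativity is structural; clip solver-level noise only
    tiny_neg = (states < 0) & (states > -100 * atol)
    states[tiny_neg] = 0.0
    return Trajectory(grid, states, scales, method, rtol, atol)


def compare_to_data(traj: Trajectory, series: MouseTimeSeries) -> pd.DataFrame:
    """Signed residuals (prediction - datum) and per-variable RMS.

    Both inputs must be nondimensional; the returned frame has one row
    per (day, variable) plus an ``rms`` column repeated per variable.
    """
    if series.frame != "nondimensional":
        raise ValueError("series must be nondimensional for comparison")
    if (series.times.min() < traj.times[0]
            or series.times.max() > traj.times[-1]):
        raise ValueError("data times outside trajectory range")
    pred = np.vstack([traj.at(t) for t in series.times])
    resid = pred - series.values
    rms = np.sqrt(np.mean(resid ** 2, axis=0))
    recs = []
    for i, t in enumerate(series.times):
        for j, v in enumerate(ode.VAR_NAMES):
            recs.append({"day": float(t), "variable": v,
                         "prediction": float(pred[i, j]),
                         "datum": float(series.values[i, j]),
                         "residual": float(resid[i, j]),
                         "rms": float(rms[j])})
    return pd.DataFrame(recs)


@dataclass(frozen=True)
class PerturbationEnvelope:
    times: np.ndarray
    baseline: np.ndarray   # (n_times, 15)
    lower: np.ndarray
    upper: np.ndarray
    param_names: tuple[str, ...]
    fraction: float
    sampling: str
    seed: int | None


def perturbation_envelope(params: ParameterSet, param_names, init,
                          fraction: float = 0.20,
                          horizon: float = DEFAULT_HORIZON, grid=None, *,
                          sampling: str = "lhs", n_samples: int = 256,
                          seed: int = 0, rtol: float = 1e-8,
                          atol: float = 1e-10) -> PerturbationEnvelope:
    """Pointwise min/max bands from multiplicative parameter perturbations.

    Each named parameter is independently scaled within
    ``[1 - fraction, 1 + fraction]``; the baseline vector is always
    included, so the unperturbed trajectory lies inside the band.
    ``sampling="corners"`` enumerates all sign corners (k <= 12 names),
    ``"lhs"`` draws a seeded Latin hypercube of ``n_samples`` points.
    """
    names = tuple(param_names)
    unknown = set(names) - set(PARAM_NAMES)
    if unknown:
        raise KeyError(f"unknown parameters: {sorted(unknown)}")
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    k = len(names)
    if sampling == "corners":
        if k > 12:
            raise ValueError("corner sampling limited to 12 parameters")
        factors = np.array(list(product((1.0 - fraction, 1.0 + fraction),
                                        repeat=k)))
    elif sampling == "lhs":
        if fraction == 0.0:
            factors = np.ones((1, k))
        else:
            u = qmc.LatinHypercube(d=k, seed=seed).random(n_samples)
            factors = 1.0 - fraction + 2.0 * fraction * u
    else:
        raise ValueError(f"unknown sampling {sampling!r}")

    base = integrate(params, init, horizon, grid, rtol=rtol, atol=atol)
    lower = base.states.copy()
    upper = base.states.copy()
    for row in factors:
        perturbed = params.replace(**{n: params[n] * f
                                      for n, f in zip(names, row)})
        traj = integrate(perturbed, init, horizon, base.times,
                         rtol=rtol, atol=atol)
        np.minimum(lower, traj.states, out=lower)
        np.maximum(upper, traj.states, out=upper)
    return PerturbationEnvelope(base.times, base.states, lower, upper,
                                names, fraction, sampling,
                                seed if sampling == "lhs" else None)
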