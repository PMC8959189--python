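"""Linear-in-parameters estimation of the 57 interaction rates.

Given the observed (nondimensional) states, every equation of the system
is linear in the rate vector theta, so stacking one row per
(mouse, time point, equation) gives a linear model ``A theta = b`` where
``b`` collects finite-difference estimates of the time derivatives.  The
unconstrained solution is ordinary least squares; nonnegativity is
enforced by a box-constrained least-squares fit with lower bound
``theta_min`` (default 1e-5).

The public surface follows the Model/Results convention:
:class:`TumorImmuneModel` wraps a dataset, its ``fit`` method returns a
:class:`TumorImmuneFit` carrying the estimates and diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from . import ode, simulate
from .data import (MouseTimeSeries, NormalizationScales, StudyDataset,
                   builtin_dataset, compute_scales, nondimensionalize)
from .parameters import N_PARAMS, PARAM_NAMES, Constants, ParameterSet

__all__ = ["LinearSystem", "TumorImmuneModel", "TumorImmuneFit",
           "finite_difference_rates", "assemble_design",
           "solve_unconstrained", "solve_bounded"]

THETA_MIN_DEFAULT = 1e-5


def finite_difference_rates(series: MouseTimeSeries) -> np.ndarray:
    """Per-time-point derivative estimates, shape (n_times, 15), per day.

    Interior points use the wide central difference
    ``(x[i+1] - x[i-1]) / (t[i+1] - t[i-1])``; the first and last points
    fall back to first-order one-sided differences.
    """
    t, x = series.times, series.values
    if t.size < 3:
        raise ValueError("need at least 3 time points for central differences")
    rates = np.empty_like(x)
    rates[0] = (x[1] - x[0]) / (t[1] - t[0])
    rates[-1] = (x[-1] - x[-2]) / (t[-1] - t[-2])
    rates[1:-1] = (x[2:] - x[:-2]) / (t[2:] - t[:-2])[:, None]
    return rates


@dataclass(frozen=True)
class LinearSystem:
    """Stacked design ``A`` (rows x 57) and derivative vector ``b``.

    ``row_index[r] = (mouse_id, day, variable)`` records provenance.
    No parameter appears inside ``A``: entries are polynomials in the
    observed data values and the fixed constants only.
    """

    A: np.ndarray
    b: np.ndarray
    row_index: tuple[tuple[int, float, str], ...]

    def __post_init__(self):
        if self.A.shape != (self.b.size, N_PARAMS):
            raise ValueError("inconsistent design shape")

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.A))

    @property
    def singular_values(self) -> np.ndarray:
        return np.linalg.svd(self.A, compute_uv=False)

    @property
    def condition_number(self) -> float:
        s = self.singular_values
        return float(s[0] / s[-1])

    def effective_rank(self, rtol: float = 1e-3) -> int:
        """Practically identifiable directions: singular values above
        ``rtol`` times the largest.  With sparse sampling the design is
        full rank at machine precision yet severely ill-conditioned, so
        this is the honest identifiability count."""
        s = self.singular_values
        return int(np.sum(s > rtol * s[0]))


def assemble_design(dataset: StudyDataset,
                    constants: Constants | None = None, *,
                    endpoints: str = "onesided") -> LinearSystem:
    """Rearrange the ODEs into the linear system at the observed states.

    ``endpoints="onesided"`` keeps one-sided derivative rows at the first
    and last sampling times (all n_times rows per mouse);
    ``"interior-only"`` restricts to the central-difference rows.
    """
    if dataset.frame != "nondimensional":
        raise ValueError("design assembly requires the nondimensional frame")
    if endpoints not in ("onesided", "interior-only"):
        raise ValueError(f"unknown endpoints mode {endpoints!r}")
    cst = constants or Constants()
    blocks, rhs_rows, index = [], [], []
    for m in dataset:
        rates = finite_difference_rates(m)
        rows = range(len(m.times)) if endpoints == "onesided" \
            else range(1, len(m.times) - 1)
        for i in rows:
            blocks.append(ode.jacobian_params(m.values[i], cst))
            rhs_rows.append(rates[i])
            index.extend((m.mouse_id, float(m.times[i]), v)
                         for v in ode.VAR_NAMES)
    A = np.vstack(blocks)
    b = np.concatenate(rhs_rows)
    return LinearSystem(A, b, tuple(index))


def solve_unconstrained(system: LinearSystem) -> tuple[np.ndarray, int]:
    """Minimum-norm least-squares solution and the numerical rank of A.

    Rank deficiency (expected with sparse sampling: 57 unknowns, few
    observations, collinear regressors) is resolved through the SVD
    pseudoinverse and surfaced via the returned rank, never hidden.
    """
    theta, _, rank, _ = np.linalg.lstsq(system.A, system.b, rcond=None)
    return theta, int(rank)


def solve_bounded(system: LinearSystem,
                  theta_min: float = THETA_MIN_DEFAULT) -> np.ndarray:
    """Box-constrained least squares: minimize ||A theta - b||^2 over
    ``theta >= theta_min`` componentwise.

    Correctness is KKT, not algorithmic: components strictly above the
    bound have (numerically) zero objective gradient, components at the
    bound a nonnegative one.
    """
    if not np.isfinite(theta_min):
        raise ValueError("theta_min must be finite")
    # BVLS is an exact active-set method; it needs rows >= columns
    method = "bvls" if system.A.shape[0] >= system.A.shape[1] else "trf"
    res = lsq_linear(system.A, system.b, bounds=(theta_min, np.inf),
                     method=method, tol=1e-12, max_iter=1000)
    if res.status <= 0:
        raise RuntimeError(f"bounded least squares failed: {res.message}")
    return np.clip(res.x, theta_min, None)


class TumorImmuneModel:
    """ODE interaction model bound to a mouse time-course dataset.

    Parameters
    ----------
    dataset : StudyDataset, dimensional frame
        Per-mouse abundance time courses (the embedded three-mouse study
        by default; see :meth:`builtin`).
    constants : Constants, optional
        Fixed carrying capacities and necrotic fraction.
    """

    def __init__(self, dataset: StudyDataset,
                 constants: Constants | None = None):
        if dataset.frame != "dimensional":
            raise ValueError("model expects the dimensional frame; scales "
                             "are derived from the data")
        self.dataset = dataset
        self.constants = constants or Constants()
        self.scales: NormalizationScales = compute_scales(dataset)
        self.dataset_nd = nondimensionalize(dataset, self.scales)

    @classmethod
    def builtin(cls, constants: Constants | None = None) -> "TumorImmuneModel":
        return cls(builtin_dataset(), constants)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       constants: Constants | None = None) -> "TumorImmuneModel":
        return cls(StudyDataset.from_dataframe(df), constants)

    def design(self, endpoints: str = "onesided") -> LinearSystem:
        return assemble_design(self.dataset_nd, self.constants,
                               endpoints=endpoints)

    def fit(self, theta_min: float = THETA_MIN_DEFAULT,
            endpoints: str = "onesided") -> "TumorImmuneFit":
        """Joint bounded least-squares fit over all mice."""
        system = self.design(endpoints)
        theta_u, rank = solve_unconstrained(system)
        theta_b = solve_bounded(system, theta_min)
        return TumorImmuneFit(self, system, theta_b, theta_u, rank,
                              theta_min, endpoints)

    def initial_state(self, mouse_id: int) -> np.ndarray:
        """Nondimensional day-0 state of one mouse."""
        m = self.dataset_nd.mouse(mouse_id)
        return m.values[0].copy()

    @property
    def mouse_ids(self) -> tuple[int, ...]:
        return tuple(m.mouse_id for m in self.dataset)


class TumorImmuneFit:
    """Estimation results: rate estimates, diagnostics and downstream
    analyses (simulation, sensitivity, bifurcation) for a fitted model."""

    def __init__(self, model: TumorImmuneModel, system: LinearSystem,
                 theta: np.ndarray, theta_unconstrained: np.ndarray,
                 rank: int, theta_min: float, endpoints: str):
        self.model = model
        self.system = system
        self.theta = theta
        self.theta_unconstrained = theta_unconstrained
        self.rank = rank
        self.theta_min = theta_min
        self.endpoints = endpoints
        self.params = ParameterSet(theta, model.constants)

    # -- diagnostics -------------------------------------------------------
    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.system.A @ self.theta - self.system.b))

    @property
    def residual_norm_unconstrained(self) -> float:
        return float(np.linalg.norm(
            self.system.A @ self.theta_unconstrained - self.system.b))

    @property
    def active_bounds(self) -> tuple[str, ...]:
        at = np.isclose(self.theta, self.theta_min, rtol=0, atol=1e-12)
        return tuple(n for n, a in zip(PARAM_NAMES, at) if a)

    @property
    def rank_deficient(self) -> bool:
        return self.rank < N_PARAMS

    def equation_residuals(self) -> pd.Series:
        """Residual 2-norm of ``A theta - b`` grouped by equation."""
        r = self.system.A @ self.theta - self.system.b
        var = pd.Index([ix[2] for ix in self.system.row_index], name="variable")
        return (pd.Series(r ** 2, index=var).groupby(level=0).sum() ** 0.5
                ).reindex(list(ode.VAR_NAMES))

    def trajectory_rms(self, **integrate_kw) -> pd.DataFrame:
        """Per-mouse, per-variable RMS between integrated dynamics and data."""
        rows = {}
        for m in self.model.dataset_nd:
            traj = self.simulate(m.mouse_id, horizon=float(m.times[-1]),
                                 **integrate_kw)
            cmp_ = simulate.compare_to_data(traj, m)
            rows[m.mouse_id] = cmp_.groupby("variable", sort=False)["rms"].first()
        return pd.DataFrame(rows).reindex(list(ode.VAR_NAMES))

    def report(self, trajectories: bool = True) -> dict:
        """JSON-serializable residual/diagnostic summary."""
        rep = {
            "n_rows": int(self.system.b.size),
            "n_params": N_PARAMS,
            "rank": self.rank,
            "rank_deficient": self.rank_deficient,
            "effective_rank": self.system.effective_rank(),
            "condition_number": self.system.condition_number,
            "theta_min": self.theta_min,
            "endpoints": self.endpoints,
            "residual_norm": self.residual_norm,
            "residual_norm_unconstrained": self.residual_norm_unconstrained,
            "active_bounds": list(self.active_bounds),
            "equation_residuals": {k: float(v) for k, v
                                   in self.equation_residuals().items()},
        }
        if trajectories:
            rms = self.trajectory_rms()
            rep["trajectory_rms"] = {str(mid): {v: float(rms.loc[v, mid])
                                                for v in ode.VAR_NAMES}
                                     for mid in rms.columns}
        return rep

    def summary(self) -> str:
        lines = [
            "Tumor-microenvironment ODE model — bounded least-squares fit",
            "=" * 62,
            f"observations (rows): {self.system.b.size:>6}    "
            f"parameters: {N_PARAMS}",
            f"numerical rank of A: {self.rank:>6}    "
            f"effective rank (rtol 1e-3): {self.system.effective_rank()}",
            f"condition number of A: {self.system.condition_number:.3g}",
            f"theta_min: {self.theta_min:g}    endpoint rows: {self.endpoints}",
            f"||A theta - b||  bounded: {self.residual_norm:.6g}   "
            f"unconstrained: {self.residual_norm_unconstrained:.6g}",
            f"parameters at the bound: {len(self.active_bounds)}",
            "-" * 62,
            f"{'parameter':<16}{'estimate':>14}{'at bound':>10}",
        ]
        at = set(self.active_bounds)
        for name, val in zip(PARAM_NAMES, self.theta):
            lines.append(f"{name:<16}{val:>14.6g}{'*' if name in at else '':>10}")
        return "\n".join(lines)

    def save_params(self, path) -> None:
        self.params.to_json(path)

    def save_report(self, path, **kw) -> None:
        with open(path, "w") as fh:
            json.dump(self.report(**kw), fh, indent=1)
            fh.write("\n")

    # -- downstream analyses ----------------------------------------------
    def simulate(self, mouse_id: int, horizon: float = simulate.DEFAULT_HORIZON,
                 **kw) -> simulate.Trajectory:
        return simulate.integrate(self.params,
                                  self.model.initial_state(mouse_id),
                                  horizon, scales=self.model.scales, **kw)

    def sensitivity(self, mouse_id: int, output: str = "cancer", **kw):
        from .sensitivity import neighborhood_average
        return neighborhood_average(self.params,
                                    self.model.initial_state(mouse_id),
                                    output=output, scales=self.model.scales,
                                    mouse_id=mouse_id, **kw)

    def bifurcation(self, param_name: str, **kw):
        from .sensitivity import bifurcation_scan
        inits = {mid: self.model.initial_state(mid)
                 for mid in self.model.mouse_ids}
        return bifurcation_scan(param_name, self.params, inits,
                                scales=self.model.scales, **kw)
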