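"""Rate-parameter vector of the tumor-microenvironment ODE model.

The model has 57 nonnegative rate parameters (per day, acting on
nondimensional abundances) plus three fixed dimensionless constants: the
cancer and adipocyte carrying capacities ``C0`` and ``A0`` and the
necrotic fraction factor ``alpha_NC``.  The canonical ordering of the 57
rates is frozen in :data:`PARAM_NAMES`; every design matrix, Jacobian
column and sensitivity vector in the package indexes against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "N_PARAMS",
    "Constants",
    "ParameterSet",
    "table3_parameters",
]

#: Canonical ordering of the 57 rate parameters: 33 production/activation
#: rates, then 21 decay/inhibition rates, then 3 constant source rates.
PARAM_NAMES: tuple[str, ...] = (
    # production / activation
    "lambda_ThH", "lambda_ThD", "lambda_ThIL12",
    "lambda_TcD", "lambda_TcIL12", "lambda_TrD",
    "lambda_DC", "lambda_DH",
    "lambda_MIL10", "lambda_MIL12", "lambda_MTh",
    "lambda_C", "lambda_CIL6", "lambda_CA", "lambda_A",
    "lambda_HD", "lambda_HN", "lambda_HM", "lambda_HTc", "lambda_HC",
    "lambda_IL12M", "lambda_IL12D", "lambda_IL12Th", "lambda_IL12Tc",
    "lambda_IL10M", "lambda_IL10D", "lambda_IL10Tr", "lambda_IL10Th",
    "lambda_IL10Tc", "lambda_IL10C",
    "lambda_IL6A", "lambda_IL6M", "lambda_IL6D",
    # decay / inhibition
    "delta_Th", "delta_Tc", "delta_Tr", "delta_TN", "delta_DN", "delta_D",
    "delta_MN", "delta_M", "delta_C", "delta_A", "delta_N", "delta_H",
    "delta_IL12", "delta_IL10", "delta_IL6",
    "delta_ThTr", "delta_ThIL10", "delta_TcTr", "delta_TcIL10",
    "delta_DC", "delta_CTc",
    # constant sources
    "A_TN", "A_DN", "A_M",
)

N_PARAMS = len(PARAM_NAMES)
assert N_PARAMS == 57

_PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}


@dataclass(frozen=True)
class Constants:
    """Fixed dimensionless constants of the nondimensional system.

    These are treated as known quantities during estimation (keeping the
    least-squares problem linear in the rates) and are never fitted.
    """

    C0: float = 2.0        # cancer carrying capacity
    A0: float = 2.0        # adipocyte carrying capacity
    alpha_NC: float = 1.5  # fraction of dying cancer cells becoming necrotic


@dataclass
class ParameterSet(Mapping[str, float]):
    """The 57 nondimensional rates plus the fixed constants.

    Behaves as a read-only name->value mapping; :attr:`values` exposes the
    underlying vector in canonical order for numerical code.
    """

    values: np.ndarray
    constants: Constants = field(default_factory=Constants)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_PARAMS,):
            raise ValueError(f"expected {N_PARAMS} rates, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("parameter vector contains non-finite entries")
        if np.any(v < 0):
            bad = [PARAM_NAMES[i] for i in np.where(v < 0)[0]]
            raise ValueError(f"negative rate(s): {bad}")
        self.values = v

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return float(self.values[_PARAM_INDEX[name]])

    def __iter__(self) -> Iterator[str]:
        return iter(PARAM_NAMES)

    def __len__(self) -> int:
        return N_PARAMS

    # -- construction / modification --------------------------------------
    @classmethod
    def from_dict(cls, mapping: Mapping[str, float],
                  constants: Constants | None = None) -> "ParameterSet":
        missing = set(PARAM_NAMES) - set(mapping)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")
        extra = set(mapping) - set(PARAM_NAMES)
        if extra:
            raise KeyError(f"unknown parameters: {sorted(extra)}")
        vec = np.array([mapping[n] for n in PARAM_NAMES], dtype=float)
        return cls(vec, constants or Constants())

    def replace(self, **updates: float) -> "ParameterSet":
        """Return a copy with the named rates replaced."""
        vec = self.values.copy()
        for name, val in updates.items():
            vec[_PARAM_INDEX[name]] = val
        return ParameterSet(vec, self.constants)

    def to_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(PARAM_NAMES, self.values)}

    # -- serialization -----------------------------------------------------
    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path, constants: Constants | None = None) -> "ParameterSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh), constants)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ParameterSet({N_PARAMS} rates, constants={self.constants})"


def table3_parameters(constants: Constants | None = None) -> ParameterSet:
    """The published fitted rate vector bundled with the package."""
    text = resources.files("pymt_tme").joinpath("table3_params.json").read_text()
    return ParameterSet.from_dict(json.loads(text), constants)
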