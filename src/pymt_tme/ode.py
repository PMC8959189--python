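"""Nondimensional right-hand side of the 15-variable tumor-microenvironment ODE.

State variables (canonical order, matching the dataset column order):

====  =======  =============================================
idx   symbol   meaning
====  =======  =============================================
0     T_N      naive T cells
1     T_h      helper T cells
2     T_c      cytotoxic cells (CD8 + activated NK)
3     T_r      regulatory T cells
4     D_N      naive dendritic cells
5     D        activated dendritic cells
6     M_N      naive macrophages (M0 + monocytes)
7     M        activated macrophages (M1 + M2)
8     C        cancer cells
9     N        necrotic cells
10    A        cancer-associated adipocytes
11    H        HMGB1
12    IL12     interleukin 12
13    IL10     interleukin 10
14    IL6      interleukin 6
====  =======  =============================================

The dynamics are mass-action activation/decay chains for the immune
compartments, logistic growth for cancer (promoted by IL-6 and
adipocytes, killed by cytotoxic cells) and adipocytes, and necrosis fed
by a fixed fraction ``alpha_NC`` of the cancer death flux.  Every
equation is *linear in the 57 rate parameters* given the state, which is
what makes the least-squares estimation in :mod:`pymt_tme.model` linear.

All functions broadcast over leading axes: ``state`` may be ``(..., 15)``
and ``theta`` ``(57,)`` or ``(..., 57)``.
"""

from __future__ import annotations

import numpy as np

from .parameters import N_PARAMS, PARAM_NAMES, Constants, ParameterSet

__all__ = [
    "VAR_NAMES",
    "N_VARS",
    "TOTAL_CELL_WEIGHTS",
    "rhs",
    "jacobian_state",
    "jacobian_params",
    "adipocyte_closed_form",
    "total_cells",
]

VAR_NAMES: tuple[str, ...] = (
    "T_N", "T_h", "T_c", "T_r", "D_N", "D", "M_N", "M",
    "C", "N", "A", "H", "IL12", "IL10", "IL6",
)
N_VARS = len(VAR_NAMES)
VAR_INDEX = {name: i for i, name in enumerate(VAR_NAMES)}

# Total-cell functional: all tumor-resident populations, naive T cells
# excluded (lymphatic compartment), naive macrophages down-weighted to 20%
# (most polarize inside the tumor), cytokines excluded.
TOTAL_CELL_WEIGHTS = np.array(
    [0.0, 1, 1, 1, 1, 1, 0.2, 1, 1, 1, 1, 0, 0, 0, 0], dtype=float
)

_PI = {name: i for i, name in enumerate(PARAM_NAMES)}


def _theta_array(params) -> tuple[np.ndarray, Constants]:
    if isinstance(params, ParameterSet):
        return params.values, params.constants
    return np.asarray(params, dtype=float), Constants()


def _validate(x: np.ndarray, theta: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValueError("state contains non-finite components")
    if np.any(x < 0):
        raise ValueError("state contains negative components")
    if not np.all(np.isfinite(theta)):
        raise ValueError("parameters contain non-finite entries")


def rhs(state, params, constants: Constants | None = None, *,
        validate: bool = True) -> np.ndarray:
    """Time derivative d(state)/dt of the nondimensional system, per day."""
    theta, c = _theta_array(params)
    constants = constants or c
    x = np.asarray(state, dtype=float)
    if x.shape[-1] != N_VARS:
        raise ValueError(f"state must have {N_VARS} components")
    if validate:
        _validate(x, theta)
    return _rhs(x, theta, constants)


def _rhs(x: np.ndarray, theta: np.ndarray, cst: Constants) -> np.ndarray:
    p = {name: theta[..., i] for name, i in _PI.items()}
    TN, Th, Tc, Tr, DN, D, MN, M, C, N, A, H, IL12, IL10, IL6 = (
        x[..., i] for i in range(N_VARS))

    act_Th = (p["lambda_ThH"] * H + p["lambda_ThD"] * D
              + p["lambda_ThIL12"] * IL12) * TN
    act_Tc = (p["lambda_TcD"] * D + p["lambda_TcIL12"] * IL12) * TN
    act_Tr = p["lambda_TrD"] * D * TN
    act_D = (p["lambda_DC"] * C + p["lambda_DH"] * H) * DN
    act_M = (p["lambda_MIL10"] * IL10 + p["lambda_MIL12"] * IL12
             + p["lambda_MTh"] * Th) * MN
    growth_C = p["lambda_C"] + p["lambda_CIL6"] * IL6 + p["lambda_CA"] * A
    death_C = p["delta_CTc"] * Tc + p["delta_C"]

    out = np.empty(np.broadcast_shapes(x.shape[:-1], theta.shape[:-1]) + (N_VARS,))
    out[..., 0] = p["A_TN"] - act_Th - act_Tc - act_Tr - p["delta_TN"] * TN
    out[..., 1] = act_Th - (p["delta_ThTr"] * Tr + p["delta_ThIL10"] * IL10
                            + p["delta_Th"]) * Th
    out[..., 2] = act_Tc - (p["delta_TcTr"] * Tr + p["delta_TcIL10"] * IL10
                            + p["delta_Tc"]) * Tc
    out[..., 3] = act_Tr - p["delta_Tr"] * Tr
    out[..., 4] = p["A_DN"] - act_D - p["delta_DN"] * DN
    out[..., 5] = act_D - (p["delta_DC"] * C + p["delta_D"]) * D
    out[..., 6] = p["A_M"] - act_M - p["delta_MN"] * MN
    out[..., 7] = act_M - p["delta_M"] * M
    out[..., 8] = growth_C * (1.0 - C / cst.C0) * C - death_C * C
    out[..., 9] = cst.alpha_NC * death_C * C - p["delta_N"] * N
    out[..., 10] = (p["lambda_A"] * A * (1.0 - A / cst.A0)
                    - p["delta_A"] * A)
    out[..., 11] = (p["lambda_HD"] * D + p["lambda_HN"] * N
                    + p["lambda_HM"] * M + p["lambda_HTc"] * Tc
                    + p["lambda_HC"] * C - p["delta_H"] * H)
    out[..., 12] = (p["lambda_IL12M"] * M + p["lambda_IL12D"] * D
                    + p["lambda_IL12Th"] * Th + p["lambda_IL12Tc"] * Tc
                    - p["delta_IL12"] * IL12)
    out[..., 13] = (p["lambda_IL10M"] * M + p["lambda_IL10D"] * D
                    + p["lambda_IL10Tr"] * Tr + p["lambda_IL10Th"] * Th
                    + p["lambda_IL10Tc"] * Tc + p["lambda_IL10C"] * C
                    - p["delta_IL10"] * IL10)
    out[..., 14] = (p["lambda_IL6A"] * A + p["lambda_IL6M"] * M
                    + p["lambda_IL6D"] * D - p["delta_IL6"] * IL6)
    return out


def jacobian_state(state, params, constants: Constants | None = None, *,
                   validate: bool = True, out: np.ndarray | None = None
                   ) -> np.ndarray:
    """Analytic ``(..., 15, 15)`` Jacobian of :func:`rhs` w.r.t. the state.

    Only the cancer, adipocyte and necrosis equations carry entries that
    are more than bilinear in the state; everything else is mass action.
    """
    theta, c = _theta_array(params)
    cst = constants or c
    x = np.asarray(state, dtype=float)
    if validate:
        _validate(x, theta)
    p = {name: theta[..., i] for name, i in _PI.items()}
    TN, Th, Tc, Tr, DN, D, MN, M, C, N, A, H, IL12, IL10, IL6 = (
        x[..., i] for i in range(N_VARS))

    shape = np.broadcast_shapes(x.shape[:-1], theta.shape[:-1])
    if out is None:
        J = np.zeros(shape + (N_VARS, N_VARS))
    else:
        J = out
        J[...] = 0.0

    act_Th = (p["lambda_ThH"] * H + p["lambda_ThD"] * D
              + p["lambda_ThIL12"] * IL12)
    act_Tc = p["lambda_TcD"] * D + p["lambda_TcIL12"] * IL12
    act_Tr = p["lambda_TrD"] * D
    act_D = p["lambda_DC"] * C + p["lambda_DH"] * H
    act_M = (p["lambda_MIL10"] * IL10 + p["lambda_MIL12"] * IL12
             + p["lambda_MTh"] * Th)
    growth_C = p["lambda_C"] + p["lambda_CIL6"] * IL6 + p["lambda_CA"] * A
    death_C = p["delta_CTc"] * Tc + p["delta_C"]
    logi_C = (1.0 - C / cst.C0) * C

    # naive T cells
    J[..., 0, 0] = -(act_Th + act_Tc + act_Tr) - p["delta_TN"]
    J[..., 0, 11] = -p["lambda_ThH"] * TN
    J[..., 0, 5] = -(p["lambda_ThD"] + p["lambda_TcD"] + p["lambda_TrD"]) * TN
    J[..., 0, 12] = -(p["lambda_ThIL12"] + p["lambda_TcIL12"]) * TN
    # helper T cells
    J[..., 1, 0] = act_Th
    J[..., 1, 1] = -(p["delta_ThTr"] * Tr + p["delta_ThIL10"] * IL10
                     + p["delta_Th"])
    J[..., 1, 3] = -p["delta_ThTr"] * Th
    J[..., 1, 13] = -p["delta_ThIL10"] * Th
    J[..., 1, 11] = p["lambda_ThH"] * TN
    J[..., 1, 5] = p["lambda_ThD"] * TN
    J[..., 1, 12] = p["lambda_ThIL12"] * TN
    # cytotoxic cells
    J[..., 2, 0] = act_Tc
    J[..., 2, 2] = -(p["delta_TcTr"] * Tr + p["delta_TcIL10"] * IL10
                     + p["delta_Tc"])
    J[..., 2, 3] = -p["delta_TcTr"] * Tc
    J[..., 2, 13] = -p["delta_TcIL10"] * Tc
    J[..., 2, 5] = p["lambda_TcD"] * TN
    J[..., 2, 12] = p["lambda_TcIL12"] * TN
    # regulatory T cells
    J[..., 3, 0] = act_Tr
    J[..., 3, 5] = p["lambda_TrD"] * TN
    J[..., 3, 3] = -p["delta_Tr"]
    # naive dendritic cells
    J[..., 4, 4] = -act_D - p["delta_DN"]
    J[..., 4, 8] = -p["lambda_DC"] * DN
    J[..., 4, 11] = -p["lambda_DH"] * DN
    # activated dendritic cells
    J[..., 5, 4] = act_D
    J[..., 5, 8] = p["lambda_DC"] * DN - p["delta_DC"] * D
    J[..., 5, 11] = p["lambda_DH"] * DN
    J[..., 5, 5] = -(p["delta_DC"] * C + p["delta_D"])
    # naive macrophages
    J[..., 6, 6] = -act_M - p["delta_MN"]
    J[..., 6, 13] = -p["lambda_MIL10"] * MN
    J[..., 6, 12] = -p["lambda_MIL12"] * MN
    J[..., 6, 1] = -p["lambda_MTh"] * MN
    # activated macrophages
    J[..., 7, 6] = act_M
    J[..., 7, 13] = p["lambda_MIL10"] * MN
    J[..., 7, 12] = p["lambda_MIL12"] * MN
    J[..., 7, 1] = p["lambda_MTh"] * MN
    J[..., 7, 7] = -p["delta_M"]
    # cancer
    J[..., 8, 8] = growth_C * (1.0 - 2.0 * C / cst.C0) - death_C
    J[..., 8, 14] = p["lambda_CIL6"] * logi_C
    J[..., 8, 10] = p["lambda_CA"] * logi_C
    J[..., 8, 2] = -p["delta_CTc"] * C
    # necrotic cells
    J[..., 9, 8] = cst.alpha_NC * death_C
    J[..., 9, 2] = cst.alpha_NC * p["delta_CTc"] * C
    J[..., 9, 9] = -p["delta_N"]
    # adipocytes
    J[..., 10, 10] = p["lambda_A"] * (1.0 - 2.0 * A / cst.A0) - p["delta_A"]
    # HMGB1
    J[..., 11, 5] = p["lambda_HD"]
    J[..., 11, 9] = p["lambda_HN"]
    J[..., 11, 7] = p["lambda_HM"]
    J[..., 11, 2] = p["lambda_HTc"]
    J[..., 11, 8] = p["lambda_HC"]
    J[..., 11, 11] = -p["delta_H"]
    # IL-12
    J[..., 12, 7] = p["lambda_IL12M"]
    J[..., 12, 5] = p["lambda_IL12D"]
    J[..., 12, 1] = p["lambda_IL12Th"]
    J[..., 12, 2] = p["lambda_IL12Tc"]
    J[..., 12, 12] = -p["delta_IL12"]
    # IL-10
    J[..., 13, 7] = p["lambda_IL10M"]
    J[..., 13, 5] = p["lambda_IL10D"]
    J[..., 13, 3] = p["lambda_IL10Tr"]
    J[..., 13, 1] = p["lambda_IL10Th"]
    J[..., 13, 2] = p["lambda_IL10Tc"]
    J[..., 13, 8] = p["lambda_IL10C"]
    J[..., 13, 13] = -p["delta_IL10"]
    # IL-6
    J[..., 14, 10] = p["lambda_IL6A"]
    J[..., 14, 7] = p["lambda_IL6M"]
    J[..., 14, 5] = p["lambda_IL6D"]
    J[..., 14, 14] = -p["delta_IL6"]
    return J


def jacobian_params(state, constants: Constants | None = None, *,
                    validate: bool = True, out: np.ndarray | None = None
                    ) -> np.ndarray:
    """``(..., 15, 57)`` Jacobian of :func:`rhs` w.r.t. the rate vector.

    The system is linear in the rates, so this matrix depends on the
    state only and satisfies ``rhs(x, theta) == jacobian_params(x) @ theta``
    exactly.  Its 15-row blocks are the building blocks of the estimation
    design matrix.
    """
    cst = constants or Constants()
    x = np.asarray(state, dtype=float)
    if validate:
        if not np.all(np.isfinite(x)):
            raise ValueError("state contains non-finite components")
        if np.any(x < 0):
            raise ValueError("state contains negative components")
    TN, Th, Tc, Tr, DN, D, MN, M, C, N, A, H, IL12, IL10, IL6 = (
        x[..., i] for i in range(N_VARS))

    if out is None:
        G = np.zeros(x.shape[:-1] + (N_VARS, N_PARAMS))
    else:
        G = out
        G[...] = 0.0

    def set_(row: int, name: str, value) -> None:
        G[..., row, _PI[name]] = value

    def add_(row: int, name: str, value) -> None:
        G[..., row, _PI[name]] += value

    logi_C = (1.0 - C / cst.C0) * C

    # activation terms enter the activated pool (+) and the naive pool (-)
    for name, val in (("lambda_ThH", H * TN), ("lambda_ThD", D * TN),
                      ("lambda_ThIL12", IL12 * TN)):
        set_(1, name, val)
        set_(0, name, -val)
    for name, val in (("lambda_TcD", D * TN), ("lambda_TcIL12", IL12 * TN)):
        set_(2, name, val)
        set_(0, name, -val)
    set_(3, "lambda_TrD", D * TN)
    set_(0, "lambda_TrD", -D * TN)
    for name, val in (("lambda_DC", C * DN), ("lambda_DH", H * DN)):
        set_(5, name, val)
        set_(4, name, -val)
    for name, val in (("lambda_MIL10", IL10 * MN), ("lambda_MIL12", IL12 * MN),
                      ("lambda_MTh", Th * MN)):
        set_(7, name, val)
        set_(6, name, -val)
    # cancer growth
    set_(8, "lambda_C", logi_C)
    set_(8, "lambda_CIL6", IL6 * logi_C)
    set_(8, "lambda_CA", A * logi_C)
    # adipocyte growth
    set_(10, "lambda_A", A * (1.0 - A / cst.A0))
    # cytokine production
    for name, val in (("lambda_HD", D), ("lambda_HN", N), ("lambda_HM", M),
                      ("lambda_HTc", Tc), ("lambda_HC", C)):
        set_(11, name, val)
    for name, val in (("lambda_IL12M", M), ("lambda_IL12D", D),
                      ("lambda_IL12Th", Th), ("lambda_IL12Tc", Tc)):
        set_(12, name, val)
    for name, val in (("lambda_IL10M", M), ("lambda_IL10D", D),
                      ("lambda_IL10Tr", Tr), ("lambda_IL10Th", Th),
                      ("lambda_IL10Tc", Tc), ("lambda_IL10C", C)):
        set_(13, name, val)
    for name, val in (("lambda_IL6A", A), ("lambda_IL6M", M),
                      ("lambda_IL6D", D)):
        set_(14, name, val)
    # natural decay
    for row, name, var in ((1, "delta_Th", Th), (2, "delta_Tc", Tc),
                           (3, "delta_Tr", Tr), (0, "delta_TN", TN),
                           (4, "delta_DN", DN), (5, "delta_D", D),
                           (6, "delta_MN", MN), (7, "delta_M", M),
                           (10, "delta_A", A), (9, "delta_N", N),
                           (11, "delta_H", H), (12, "delta_IL12", IL12),
                           (13, "delta_IL10", IL10), (14, "delta_IL6", IL6)):
        set_(row, name, -var)
    # cancer death feeds necrosis via alpha_NC
    set_(8, "delta_C", -C)
    add_(9, "delta_C", cst.alpha_NC * C)
    set_(8, "delta_CTc", -Tc * C)
    add_(9, "delta_CTc", cst.alpha_NC * Tc * C)
    # inhibition terms
    set_(1, "delta_ThTr", -Tr * Th)
    set_(1, "delta_ThIL10", -IL10 * Th)
    set_(2, "delta_TcTr", -Tr * Tc)
    set_(2, "delta_TcIL10", -IL10 * Tc)
    set_(5, "delta_DC", -C * D)
    # constant sources
    set_(0, "A_TN", np.broadcast_to(1.0, TN.shape) if TN.ndim else 1.0)
    set_(4, "A_DN", np.broadcast_to(1.0, TN.shape) if TN.ndim else 1.0)
    set_(6, "A_M", np.broadcast_to(1.0, TN.shape) if TN.ndim else 1.0)
    return G


def adipocyte_closed_form(A_init: float, lambda_A: float, delta_A: float,
                          A0: float = 2.0, t=0.0) -> np.ndarray | float:
    """Exact solution of the independent adipocyte logistic equation.

    ``dA/dt = lambda_A * A * (1 - A/A0) - delta_A * A`` is logistic with
    effective rate ``r = lambda_A - delta_A`` and effective capacity
    ``K = A0 * (1 - delta_A/lambda_A)``; the ``r = 0`` case degenerates to
    the algebraic decay ``A(t) = A_init / (1 + lambda_A*A_init*t/A0)``.
    """
    if A_init < 0:
        raise ValueError("A_init must be nonnegative")
    if lambda_A < 0 or delta_A < 0:
        raise ValueError("rates must be nonnegative")
    t = np.asarray(t, dtype=float)
    r = lambda_A - delta_A
    q = lambda_A / A0  # quadratic loss coefficient
    if r == 0.0:
        res = A_init / (1.0 + q * A_init * t)
    else:
        # A(t) = r A0 e^{rt} / (r + q A0 (e^{rt} - 1)), A0 := A_init
        res = A_init * np.exp(r * t) / (1.0 + q * A_init * np.expm1(r * t) / r)
    return res if res.ndim else float(res)


def total_cells(state) -> np.ndarray | float:
    """Total tumor-resident cell count of a *dimensional* state.

    ``T_h + T_c + T_r + D_N + D + 0.2*M_N + M + C + N + A`` — naive
    T cells and the four cytokines are excluded.
    """
    x = np.asarray(state, dtype=float)
    res = x @ TOTAL_CELL_WEIGHTS
    return res if np.ndim(res) else float(res)
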