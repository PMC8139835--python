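"""Model equations, steady states, fixed points and local stability.

The membrane equation is

    Cin dV/dt = Gin (Vr - V) + GNat m^3 h (ENa - V) + GNap mp^3 s (ENa - V)
                + GKdr n^3 (EK - V) + GA mA_inf(V) hA (EK - V) + I

with every gate x relaxing to its sigmoid steady state x_inf(V) with time
constant tau_x (voltage-dependent for h).  The A-current activation mA is
instantaneous (algebraic).  With gates eliminated at steady state the fixed
points of the model are the roots of a scalar current-balance relation in V,
which is how :func:`find_fixed_points` locates them (bracketing on a dense
voltage grid, then bisection); stability comes from the eigenvalues of a
finite-difference Jacobian restricted to the dynamically active variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from ._kernels import deriv as _deriv_kernel
from .params import GateSpec, ModelParameters

__all__ = [
    "STATE_NAMES",
    "FixedPoint",
    "steady_state",
    "steady_state_vector",
    "rhs",
    "membrane_current",
    "find_fixed_points",
    "jacobian",
    "iv_fixed_point_curve",
]

STATE_NAMES = ("V", "m", "h", "mp", "s", "n", "hA")

#: |Re lambda| below this is reported as marginal rather than classified
MARGINAL_TOL = 1e-9


def steady_state(gate: GateSpec, v: Union[float, np.ndarray]):
    """Sigmoid steady state x_inf(V) = 1/(1 + exp(-(V - Vx)/kx))."""
    return gate.steady_state(v)


def steady_state_vector(
    v: float, params: ModelParameters, s: Optional[float] = None
) -> np.ndarray:
    """Full state with every gate at its steady state for voltage ``v``.

    ``s`` freezes the slow-inactivation gate at a given level; by default it
    is 1 without slow inactivation and s_inf(V) with it.
    """
    g = params.gates
    if s is None:
        s = float(g["s"].steady_state(v)) if params.include_slow_inactivation else 1.0
    return np.array(
        [
            v,
            float(g["m"].steady_state(v)),
            float(g["h"].steady_state(v)),
            float(g["mp"].steady_state(v)),
            s,
            float(g["n"].steady_state(v)),
            float(g["hA"].steady_state(v)),
        ]
    )


def rhs(
    state: np.ndarray, params: ModelParameters, i_ext: Optional[float] = None
) -> np.ndarray:
    """Time derivative of [V, m, h, mp, s, n, hA]."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state passed to rhs")
    return _deriv_kernel(
        state, params.pack(), params.i if i_ext is None else float(i_ext)
    )


def membrane_current(
    v: Union[float, np.ndarray],
    params: ModelParameters,
    s: float = 1.0,
    i_ext: Optional[float] = None,
) -> Union[float, np.ndarray]:
    """Steady-state current balance F(V) in pA (Cin dV/dt with gates at x_inf).

    The slow-inactivation gate is treated as a frozen parameter ``s`` (it is a
    slow variable; for the basic model s = 1).  Roots of F are the fixed
    points of the fast subsystem.
    """
    g = params.gates
    i = params.i if i_ext is None else i_ext
    ga = params.ga if params.include_ia else 0.0
    return (
        params.gin * (params.vr - v)
        + params.gnat * g["m"].steady_state(v) ** 3 * g["h"].steady_state(v) * (params.ena - v)
        + params.gnap * g["mp"].steady_state(v) ** 3 * s * (params.ena - v)
        + params.gkdr * g["n"].steady_state(v) ** 3 * (params.ek - v)
        + ga * g["mA"].steady_state(v) * g["hA"].steady_state(v) * (params.ek - v)
        + i
    )


def active_indices(params: ModelParameters) -> list:
    """Indices of dynamically active state variables for stability analysis.

    The slow gate s is treated as frozen (fast-subsystem analysis); hA only
    participates when IA is included.
    """
    idx = [0, 1, 2, 3, 5]
    if params.include_ia:
        idx.append(6)
    return idx


def jacobian(
    state: np.ndarray,
    params: ModelParameters,
    i_ext: Optional[float] = None,
    eps: float = 1e-6,
) -> np.ndarray:
    """Central finite-difference Jacobian restricted to active variables."""
    idx = active_indices(params)
    n = len(idx)
    jac = np.empty((n, n))
    state = np.asarray(state, dtype=float)
    for col, j in enumerate(idx):
        up = state.copy()
        dn = state.copy()
        up[j] += eps
        dn[j] -= eps
        df = (rhs(up, params, i_ext) - rhs(dn, params, i_ext)) / (2 * eps)
        jac[:, col] = df[idx]
    return jac


@dataclass(frozen=True)
class FixedPoint:
    """A fixed point of the fast subsystem with its local stability."""

    state: np.ndarray          # full 7-component state
    stable: bool
    eigenvalues: np.ndarray    # of the active-variable Jacobian
    marginal: bool = False     # leading |Re| below MARGINAL_TOL

    @property
    def v(self) -> float:
        return float(self.state[0])

    @property
    def leading_complex_real(self) -> float:
        """Largest real part among complex-conjugate eigenvalue pairs."""
        cplx = self.eigenvalues[np.abs(self.eigenvalues.imag) > 1e-12]
        return float(np.max(cplx.real)) if cplx.size else -np.inf


def _bracketed_roots(
    fun, grid: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> list:
    vals = fun(grid)
    roots = []
    for i in range(len(grid) - 1):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if fa == 0.0:
            roots.append(float(a))
            continue
        if fa * fb < 0:
            for _ in range(max_iter):
                c = 0.5 * (a + b)
                fc = fun(np.array([c]))[0]
                if fa * fc <= 0:
                    b = c
                else:
                    a, fa = c, fc
                if b - a < tol:
                    break
            roots.append(0.5 * (a + b))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    return roots


def find_fixed_points(
    params: ModelParameters,
    s_frozen: float = 1.0,
    v_range: tuple = (-100.0, 40.0),
    n_grid: int = 2001,
    v_tol: float = 1e-6,
) -> list:
    """All fixed points of the fast subsystem, with stability flags.

    Returns a list of :class:`FixedPoint` sorted by voltage (1 or 3 entries
    for this model).  With slow inactivation enabled, ``s_frozen`` is the
    frozen value of the slow gate.
    """
    fun = lambda v: membrane_current(v, params, s=s_frozen)
    grid = np.linspace(v_range[0], v_range[1], n_grid)
    out = []
    act = active_indices(params)
    for v_root in _bracketed_roots(fun, grid, tol=v_tol):
        state = steady_state_vector(v_root, params, s=s_frozen)
        res = rhs(state, params)[act]  # the frozen slow gate may drift
        if np.max(np.abs(res)) > 1e-3:
            raise ArithmeticError(
                f"root finder did not converge at V={v_root:.3f} mV "
                f"(residual {np.max(np.abs(res)):.2e})"
            )
        eig = np.linalg.eigvals(jacobian(state, params))
        lead = float(np.max(eig.real))
        out.append(
            FixedPoint(
                state=state,
                stable=lead < 0,
                eigenvalues=eig,
                marginal=abs(lead) < MARGINAL_TOL,
            )
        )
    return out


def iv_fixed_point_curve(
    params: ModelParameters,
    sweep: str,
    values: Sequence[float],
    s_frozen: float = 1.0,
) -> "np.recarray":
    """Fixed-point branches along a one-parameter sweep.

    ``sweep`` is one of {"i", "gnap", "gkdr"}.  Returns a record array with
    fields (param, v, stable): one row per (parameter value, root).  An
    S-shaped (bistable) curve shows up as parameter values with three rows.
    """
    if sweep not in ("i", "gnap", "gkdr"):
        raise ValueError("sweep parameter must be one of i, gnap, gkdr")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sweep range")
    rows = []
    for val in values:
        p = params.with_(**{sweep: float(val)})
        for fp in find_fixed_points(p, s_frozen=s_frozen):
            rows.append((float(val), fp.v, fp.stable))
    rec = np.array(rows, dtype=[("param", float), ("v", float), ("stable", bool)])
    return rec.view(np.recarray)
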