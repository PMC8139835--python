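"""Bifurcation analysis of the V1R model.

Two complementary tools are combined:

* Fixed-point bifurcations (Hopf, folds) are located analytically from the
  scalar steady-state current balance and the eigenvalues of the Jacobian,
  bisected along the swept parameter.
* Saddle-node (fold) bifurcations of limit cycles are located by
  attractor-following continuation: the model is simulated at successive
  parameter values with initial conditions inherited from the neighbouring
  converged cycle, a 2 s transient is discarded, and a sustained oscillation
  is declared when the peak-to-trough voltage span of the remaining window
  exceeds 20 mV.  The fold is then bisected to the requested resolution.

The repetitive-firing (RS) range of this model is bounded by folds of limit
cycles (SN1, SN2) lying outside a pair of subcritical Hopf bifurcations
(HB1 on the quiescent state, HB2 on the depolarized plateau), so bistable
windows quiescence/spiking and plateau/spiking flank the RS range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import find_peaks

from ._kernels import run_current_clamp
from .model import FixedPoint, find_fixed_points, steady_state_vector
from .params import ModelParameters

__all__ = [
    "BifurcationPoint",
    "hopf_scan",
    "limit_cycle_fold_scan",
    "firing_rate",
    "firing_rate_curve",
    "classify_cell",
    "two_parameter_map",
    "ActivityMap",
    "bistability_region",
]

#: oscillation criterion: sustained peak-to-trough span, mV
OSC_SPAN_MV = 20.0


@dataclass(frozen=True)
class BifurcationPoint:
    kind: str           # "HopfFixedPoint" | "FoldLimitCycle" | "FoldFixedPoint"
    parameter: str
    value: float
    v: Optional[float] = None     # voltage at the bifurcating fixed point
    branch: str = ""              # "quiescent" | "plateau" | "cycle"
    direction: str = ""           # "destabilizing" | "stabilizing" (sweep up)
    eigenvalue: Optional[complex] = None
    cycle_state: Optional[np.ndarray] = None  # a state on the last converged cycle


# ---------------------------------------------------------------------------
# Hopf bifurcations of fixed points
# ---------------------------------------------------------------------------

def _branch_fixed_point(params: ModelParameters, branch: str) -> Optional[FixedPoint]:
    fps = find_fixed_points(params)
    if not fps:
        return None
    fps.sort(key=lambda fp: fp.v)
    return fps[0] if branch == "quiescent" else fps[-1]


def _lead_re(params: ModelParameters, sweep: str, value: float, branch: str) -> float:
    fp = _branch_fixed_point(params.with_(**{sweep: float(value)}), branch)
    return -np.inf if fp is None else fp.leading_complex_real


def hopf_scan(
    params: ModelParameters,
    sweep: str,
    values: Sequence[float],
    branch: str = "quiescent",
    tol: float = 1e-3,
) -> List[BifurcationPoint]:
    """All Hopf bifurcations of the chosen fixed-point branch along a sweep.

    The branch ("quiescent" = lowest-voltage root, "plateau" = highest) is
    tracked along the coarse grid ``values``; each sign change of the real
    part of the leading complex-conjugate eigenvalue pair is bisected to
    ``tol`` in the swept parameter.  Returns an empty list if the pair never
    crosses the imaginary axis (e.g. a purely passive model).
    """
    values = np.asarray(values, dtype=float)
    res = [_lead_re(params, sweep, v, branch) for v in values]
    points: List[BifurcationPoint] = []
    for i in range(len(values) - 1):
        r0, r1 = res[i], res[i + 1]
        if not (np.isfinite(r0) and np.isfinite(r1)) or np.sign(r0) == np.sign(r1):
            continue
        a, b, fa = values[i], values[i + 1], r0
        while b - a > tol:
            c = 0.5 * (a + b)
            fc = _lead_re(params, sweep, c, branch)
            if np.sign(fa) != np.sign(fc):
                b = c
            else:
                a, fa = c, fc
        x = 0.5 * (a + b)
        fp = _branch_fixed_point(params.with_(**{sweep: x}), branch)
        eig = fp.eigenvalues[np.abs(fp.eigenvalues.imag) > 1e-12]
        lead = eig[np.argmax(eig.real)] if eig.size else None
        points.append(
            BifurcationPoint(
                kind="HopfFixedPoint",
                parameter=sweep,
                value=float(x),
                v=fp.v,
                branch=branch,
                direction="destabilizing" if r1 > r0 else "stabilizing",
                eigenvalue=complex(lead) if lead is not None else None,
            )
        )
    return points


# ---------------------------------------------------------------------------
# Limit cycles by attractor-following simulation
# ---------------------------------------------------------------------------

def _simulate(
    params: ModelParameters,
    y0: np.ndarray,
    duration: float,
    dt: float = 0.01,
    stride: int = 5,
) -> np.ndarray:
    """Integrate in place; returns recorded states (y0 is advanced)."""
    n = int(round(duration / dt))
    out = np.empty((n // stride + 1, 7))
    code = run_current_clamp(y0, params.pack(), params.i, dt, n, stride, out)
    if code != 0:
        raise ArithmeticError("integration diverged during cycle continuation")
    return out


def _oscillates(
    params: ModelParameters,
    y0: np.ndarray,
    transient: float = 2000.0,
    window: float = 1000.0,
    dt: float = 0.01,
) -> Tuple[bool, np.ndarray, np.ndarray]:
    """(sustained oscillation?, end state, last-window V samples).

    The criterion requires a peak-to-trough span > OSC_SPAN_MV over both
    halves of the measurement window, which rejects decaying subthreshold
    ringing near a subcritical Hopf point.
    """
    y = np.asarray(y0, dtype=float).copy()
    _simulate(params, y, transient, dt=dt, stride=50)
    rec = _simulate(params, y, window, dt=dt, stride=5)
    v = rec[:, 0]
    half = len(v) // 2
    osc = (np.ptp(v[:half]) > OSC_SPAN_MV) and (np.ptp(v[half:]) > OSC_SPAN_MV)
    return osc, y, v


def _spiking_seed(params: ModelParameters) -> np.ndarray:
    """Initial condition biased toward the spiking attractor: rest state
    kicked by a brief suprathreshold trajectory."""
    fps = sorted(find_fixed_points(params), key=lambda fp: fp.v)
    y = fps[0].state.copy()
    y[0] += 5.0
    return y


def limit_cycle_fold_scan(
    params: ModelParameters,
    sweep: str,
    values: Tuple[float, float],
    side: str = "onset",
    resolution: float = 1e-3,
    interior: Optional[float] = None,
    transient: float = 2000.0,
    dt: float = 0.01,
) -> Optional[BifurcationPoint]:
    """Fold of limit cycles bounding the repetitive-firing range.

    ``values`` brackets the search; ``interior`` is a parameter value where a
    stable cycle is expected (found by a coarse scan when omitted).  The
    cycle is continued toward the requested ``side`` ("onset" = low end,
    "offset" = high end) by inheriting the state of the last converged
    cycle, then the boundary is bisected to ``resolution``; the trial at the
    midpoint always starts from the inside (converged-cycle) state so the
    test probes existence of the cycle attractor, not its basin.
    Returns None if no sustained cycle is found in the bracket.
    """
    def check(p, y):
        # a slowly decaying transient can masquerade as a cycle close to the
        # fold; require the oscillation to survive a second transient+window
        osc, y1, _ = _oscillates(p, y, transient=transient, dt=dt)
        if not osc:
            return False, y1
        osc2, y2, _ = _oscillates(p, y1, transient=transient, dt=dt)
        return osc2, y2

    lo, hi = float(values[0]), float(values[1])
    if interior is None:
        for x in np.linspace(lo, hi, 11)[1:-1]:
            p = params.with_(**{sweep: float(x)})
            osc, y = check(p, _spiking_seed(p))
            if osc:
                interior = float(x)
                y_cycle = y
                break
        else:
            return None
    else:
        p = params.with_(**{sweep: float(interior)})
        osc, y_cycle = check(p, _spiking_seed(p))
        if not osc:
            return None

    # march outward from the interior point, inheriting the cycle state
    edge = lo if side == "onset" else hi
    step = (edge - interior) / 12.0
    x_in, y_in = interior, y_cycle
    x_out = None
    x = interior
    while x_out is None:
        x_next = x + step
        past_edge = (x_next <= edge) if side == "onset" else (x_next >= edge)
        if past_edge:
            x_next = edge
        p = params.with_(**{sweep: float(x_next)})
        osc, y_end = check(p, y_in)
        if osc:
            x_in, y_in = x_next, y_end
            if x_next == edge:
                return None  # cycle persists to the bracket edge: no fold inside
        else:
            x_out = x_next
        x = x_next

    # bisect, always restarting from the inherited inside-cycle state
    while abs(x_out - x_in) > resolution:
        c = 0.5 * (x_in + x_out)
        p = params.with_(**{sweep: float(c)})
        osc, y_end = check(p, y_in)
        if osc:
            x_in, y_in = c, y_end
        else:
            x_out = c
    return BifurcationPoint(
        kind="FoldLimitCycle",
        parameter=sweep,
        value=float(0.5 * (x_in + x_out)),
        branch="cycle",
        direction="onset" if side == "onset" else "offset",
        cycle_state=y_in.copy(),
    )


def firing_rate(
    params: ModelParameters,
    duration: float = 10000.0,
    transient: float = 2000.0,
    dt: float = 0.01,
    y0: Optional[np.ndarray] = None,
) -> float:
    """Steady firing rate (Hz) on the attractor, from mean inter-spike
    interval after transient discard; 0.0 if fewer than 3 spikes."""
    y = _spiking_seed(params) if y0 is None else np.asarray(y0, float).copy()
    _simulate(params, y, transient, dt=dt, stride=50)
    rec = _simulate(params, y, duration - transient, dt=dt, stride=5)
    v = rec[:, 0]
    peaks, _ = find_peaks(v, prominence=OSC_SPAN_MV)
    if len(peaks) < 3:
        return 0.0
    isi = np.diff(peaks) * dt * 5
    return 1000.0 / float(np.mean(isi))


def firing_rate_curve(
    params: ModelParameters, sweep: str, values: Sequence[float]
) -> np.ndarray:
    """Firing rate along a parameter sweep (rows: parameter, rate Hz)."""
    rows = []
    y = None
    for x in values:
        p = params.with_(**{sweep: float(x)})
        rate = firing_rate(p, y0=y)
        rows.append((float(x), rate))
    return np.array(rows)


# ---------------------------------------------------------------------------
# Two-parameter activity map
# ---------------------------------------------------------------------------

PLATEAU_V_MV = -35.0  # fixed points above this count as depolarized plateaus


def classify_cell(params: ModelParameters, dt: float = 0.01) -> str:
    """Attractor census at one (GNap, GKdr) point.

    Simulates from three canonical initial conditions (rest, depolarized,
    perturbed rest) and inspects the attractors reached together with the
    stable fixed points.  Returns one of {"SS", "RS", "PP", "RS+SS",
    "RS+PP"} — SS meaning the only attractor is the quiescent state.
    """
    fps = find_fixed_points(params)
    stable = [fp for fp in fps if fp.stable]
    has_q = any(fp.v <= PLATEAU_V_MV for fp in stable)
    has_p = any(fp.v > PLATEAU_V_MV for fp in stable)
    seeds = [steady_state_vector(-60.0, params), steady_state_vector(-10.0, params)]
    if fps:
        kicked = sorted(fps, key=lambda fp: fp.v)[0].state.copy()
        kicked[0] += 5.0
        seeds.append(kicked)
    has_cycle = False
    for y0 in seeds:
        osc, _, _ = _oscillates(params, y0, transient=1500.0, window=800.0, dt=dt)
        if osc:
            has_cycle = True
            break
    if has_cycle:
        if has_p:
            return "RS+PP"
        if has_q:
            return "RS+SS"
        return "RS"
    return "PP" if has_p else "SS"


@dataclass
class ActivityMap:
    gnap: np.ndarray
    gkdr: np.ndarray
    labels: np.ndarray          # (len(gkdr), len(gnap)) object array
    hb_quiescent: list = field(default_factory=list)  # (gkdr, gnap) pairs
    hb_plateau: list = field(default_factory=list)
    sn_onset: list = field(default_factory=list)
    sn_offset: list = field(default_factory=list)

    def label_at(self, gnap: float, gkdr: float) -> str:
        i = int(np.argmin(np.abs(self.gkdr - gkdr)))
        j = int(np.argmin(np.abs(self.gnap - gnap)))
        return self.labels[i, j]

    def rs_possible(self, gnap: float, gkdr: float) -> bool:
        return "RS" in self.label_at(gnap, gkdr)


def two_parameter_map(
    params: ModelParameters,
    gnap_range: Tuple[float, float] = (0.0, 2.5),
    gkdr_range: Tuple[float, float] = (0.5, 25.0),
    n_gnap: int = 26,
    n_gkdr: int = 26,
    trace_boundaries: bool = False,
    fold_resolution: float = 0.01,
) -> ActivityMap:
    """Activity map in the GNap-GKdr plane at fixed injected current.

    Per-cell labels come from the attractor census of :func:`classify_cell`.
    With ``trace_boundaries`` the HB curves (eigenvalue bisection) and the
    folds of limit cycles are continued along the GKdr grid.
    """
    gnap = np.linspace(*gnap_range, n_gnap)
    gkdr = np.linspace(*gkdr_range, n_gkdr)
    labels = np.empty((n_gkdr, n_gnap), dtype=object)
    for i, gk in enumerate(gkdr):
        for j, gn in enumerate(gnap):
            labels[i, j] = classify_cell(params.with_(gnap=float(gn), gkdr=float(gk)))
    amap = ActivityMap(gnap=gnap, gkdr=gkdr, labels=labels)
    if trace_boundaries:
        scan_vals = np.linspace(max(gnap_range[0], 1e-3), gnap_range[1], 26)
        for gk in gkdr:
            p = params.with_(gkdr=float(gk))
            for pt in hopf_scan(p, "gnap", scan_vals, branch="quiescent"):
                if pt.direction == "destabilizing":
                    amap.hb_quiescent.append((float(gk), pt.value))
                else:
                    amap.hb_plateau.append((float(gk), pt.value))
            on = limit_cycle_fold_scan(
                p, "gnap", gnap_range, side="onset", resolution=fold_resolution
            )
            off = limit_cycle_fold_scan(
                p, "gnap", gnap_range, side="offset", resolution=fold_resolution
            )
            if on:
                amap.sn_onset.append((float(gk), on.value))
            if off:
                amap.sn_offset.append((float(gk), off.value))
    return amap


# ---------------------------------------------------------------------------
# Quiescence/plateau bistability in the I-GNap plane
# ---------------------------------------------------------------------------

def _coexistence_window(
    params: ModelParameters, i_range: Tuple[float, float], tol: float = 1e-3
) -> Optional[Tuple[float, float]]:
    """I-interval where two stable fixed points (quiescent + plateau)
    coexist, refined by bisection on the window edges."""

    def n_stable(i_val: float) -> int:
        fps = find_fixed_points(params.with_(i=float(i_val)))
        return sum(fp.stable for fp in fps)

    grid = np.linspace(i_range[0], i_range[1], 161)
    flags = np.array([n_stable(i) >= 2 for i in grid])
    if not flags.any():
        return None
    idx = np.where(flags)[0]
    lo_in, hi_in = grid[idx[0]], grid[idx[-1]]

    def bisect(a, b, inside_at_b):
        # invariant: coexistence holds at exactly one end
        while b - a > tol:
            c = 0.5 * (a + b)
            if (n_stable(c) >= 2) == inside_at_b:
                b = c
            else:
                a = c
        return 0.5 * (a + b)

    lo = bisect(grid[idx[0] - 1], lo_in, True) if idx[0] > 0 else lo_in
    hi = (
        bisect(hi_in, grid[idx[-1] + 1], False)
        if idx[-1] < len(grid) - 1
        else hi_in
    )
    return float(lo), float(hi)


def bistability_region(
    params: ModelParameters,
    gnap_values: Sequence[float],
    i_range: Tuple[float, float] = (-20.0, 20.0),
    tol: float = 1e-3,
) -> dict:
    """Quiescence/plateau bistability domain in the I-GNap plane.

    For each GNap the coexistence window of two stable fixed points over
    ``i_range`` is computed from the steady-state current balance; the
    minimal GNap admitting any coexistence is refined by bisection.  The
    window's lower edge is the fold of fixed points where the plateau state
    appears, the upper edge the subcritical Hopf where it destabilizes.
    """
    windows = {}
    for gn in gnap_values:
        w = _coexistence_window(params.with_(gnap=float(gn)), i_range, tol=tol)
        if w is not None:
            windows[float(gn)] = w
    gnap_min = None
    if windows:
        have = sorted(windows)
        lo = have[0]
        candidates = [g for g in gnap_values if g < lo]
        a = max(candidates) if candidates else lo - 0.2
        b = lo
        while b - a > tol:
            c = 0.5 * (a + b)
            if _coexistence_window(params.with_(gnap=float(c)), i_range, tol=0.02):
                b = c
            else:
                a = c
        gnap_min = float(0.5 * (a + b))
    return {"windows": windows, "gnap_min": gnap_min}
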