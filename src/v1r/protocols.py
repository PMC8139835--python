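"""In-silico electrophysiology: current-clamp and voltage-clamp protocols.

The deterministic engine integrates the model with a fixed-step fourth-order
Runge–Kutta scheme (default dt = 0.01 ms, well below the fastest gating time
constant of 1.5 ms).  Protocols mirror the experimental ones: 2 s
depolarizing current steps for firing-pattern characterization, voltage
steps after conditioning prepulses for IKdr/IA separation, and a slow
depolarizing voltage ramp (70 mV/s) for INap measurement.  Pharmacological
manipulations (TTX, 4-AP) are emulated as parameter scalings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ._kernels import run_current_clamp, run_voltage_clamp
from .model import find_fixed_points, steady_state_vector
from .params import ModelParameters

__all__ = [
    "Protocol",
    "Trace",
    "integrate",
    "settle",
    "current_step_family",
    "vclamp_step_protocol",
    "ramp_inap_protocol",
    "apply_pharmacology",
]

CURRENT_NAMES = ("leak", "nat", "nap", "kdr", "a")


@dataclass(frozen=True)
class Protocol:
    """An ordered list of (duration_ms, command) segments.

    In current clamp the command is an injected current in pA; in voltage
    clamp it is either a holding potential in mV or a ("ramp", v0, v1) tuple
    swept linearly over the segment.  ``holding`` applies before the first
    segment (used to settle initial conditions).
    """

    mode: str  # "current_clamp" | "voltage_clamp"
    segments: Tuple[Tuple[float, object], ...]
    holding: float = 0.0
    dt: float = 0.01
    record_stride: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.dt <= 0 or self.dt > 0.05:
            raise ValueError("dt must be in (0, 0.05] ms")
        for dur, _ in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "segments": [list(s) for s in self.segments],
            "holding": self.holding,
            "dt": self.dt,
            "record_stride": self.record_stride,
        }


@dataclass
class Trace:
    """A simulated recording with its provenance.

    ``v`` is the membrane potential (current clamp).  In voltage clamp ``v``
    is the command potential and ``i`` the recorded clamp current
    (outward-positive); ``currents`` holds the per-conductance decomposition
    (leak, INat, INap, IKdr, IA).  ``states`` stores the gating variables at
    the recorded samples for current-clamp runs.
    """

    t: np.ndarray
    v: np.ndarray
    command: np.ndarray
    dt: float
    i: Optional[np.ndarray] = None
    currents: Optional[np.ndarray] = None
    states: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def pulse_window(self) -> Optional[Tuple[float, float]]:
        w = self.meta.get("pulse_window")
        return tuple(w) if w is not None else None

    def to_csv(self, path: Union[str, Path]) -> None:
        path = Path(path)
        cols = {"t_ms": self.t}
        if self.i is not None:
            cols["I_pA"] = self.i
        else:
            cols["V_mV"] = self.v
        cols["command"] = self.command
        pd.DataFrame(cols).to_csv(path, index=False)
        sidecar = {
            "params": self.params,
            "protocol": self.protocol,
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, default=float)
        )


def settle(
    params: ModelParameters, i_hold: float = 0.0, duration: float = 2000.0
) -> np.ndarray:
    """State after ``duration`` ms at constant holding current.

    A settling simulation (rather than an analytic steady state) so that the
    same code path serves the slow-inactivation variant, whose rest state is
    reached only on the tau_s time scale.
    """
    fps = find_fixed_points(params.with_(i=i_hold))
    stable = [fp for fp in fps if fp.stable]
    y = (min(stable, key=lambda fp: fp.v).state.copy() if stable
         else steady_state_vector(params.vr, params))
    if params.include_slow_inactivation:
        y[4] = float(params.gates["s"].steady_state(y[0]))
    dt = 0.02
    n = int(round(duration / dt))
    out = np.empty((2, 7))
    code = run_current_clamp(y, params.pack(), i_hold, dt, n, n, out)
    if code != 0:
        raise ArithmeticError("settling simulation diverged")
    return y


def integrate(
    params: ModelParameters,
    protocol: Protocol,
    y0: Optional[np.ndarray] = None,
) -> Trace:
    """Run a current-clamp protocol with fixed-step RK4.

    Initial conditions default to a 2 s settling run at the holding current.
    Raises ArithmeticError with a diagnostic if the solution loses finiteness
    (step size too large for the parameter regime).
    """
    if protocol.mode != "current_clamp":
        raise ValueError("integrate() expects a current-clamp protocol")
    p = params.pack()
    dt = protocol.dt
    stride = protocol.record_stride
    y = settle(params, protocol.holding).copy() if y0 is None else np.asarray(y0, float).copy()
    t_parts, v_parts, c_parts, s_parts = [], [], [], []
    t0 = 0.0
    for seg_idx, (dur, cmd) in enumerate(protocol.segments):
        n = int(round(dur / dt))
        n_rec = n // stride + 1
        out = np.empty((n_rec, 7))
        code = run_current_clamp(y, p, float(cmd), dt, n, stride, out)
        if code != 0:
            raise ArithmeticError(
                f"integration diverged in segment {seg_idx} (I = {cmd} pA); "
                f"reduce dt (currently {dt} ms)"
            )
        tseg = t0 + np.arange(n_rec) * dt * stride
        first = 1 if t_parts else 0  # drop duplicated boundary sample
        t_parts.append(tseg[first:])
        v_parts.append(out[first:, 0])
        s_parts.append(out[first:])
        c_parts.append(np.full(n_rec - first, float(cmd)))
        t0 += n * dt
    states = np.concatenate(s_parts)
    return Trace(
        t=np.concatenate(t_parts),
        v=np.concatenate(v_parts),
        command=np.concatenate(c_parts),
        dt=dt * stride,
        states=states,
        params=params.to_dict(),
        protocol=protocol.to_dict(),
    )


def current_step_family(
    params: ModelParameters,
    amplitudes: Sequence[float],
    duration: float = 2000.0,
    pre: float = 500.0,
    post: float = 500.0,
    holding: float = 0.0,
    dt: float = 0.01,
) -> List[Trace]:
    """One 2 s (by default) depolarizing current step per amplitude.

    Each step starts from the holding steady state, emulating the long
    interpulse intervals used experimentally.  The pulse window is recorded
    in ``trace.meta['pulse_window']``.
    """
    traces = []
    y_rest = settle(params, holding)
    for amp in amplitudes:
        if amp < 0:
            raise ValueError("step amplitudes must be >= 0")
        proto = Protocol(
            mode="current_clamp",
            segments=((pre, holding), (duration, amp), (post, holding)),
            holding=holding,
            dt=dt,
        )
        tr = integrate(params, proto, y0=y_rest)
        tr.meta["pulse_window"] = (pre, pre + duration)
        tr.meta["amplitude_pa"] = float(amp)
        traces.append(tr)
    return traces


def _vclamp_run(
    params: ModelParameters,
    segments: Sequence[Tuple[float, object]],
    v_init: float,
    dt: float,
    stride: int,
    leak_subtracted: bool,
) -> Trace:
    # build command waveform at half-step resolution
    pieces = []
    n_total = 0
    for dur, cmd in segments:
        n = int(round(dur / dt))
        if isinstance(cmd, (tuple, list)):
            tag, v0, v1 = cmd
            if tag != "ramp":
                raise ValueError(f"unknown voltage command {cmd!r}")
            seg = np.linspace(v0, v1, 2 * n + 1)
        else:
            seg = np.full(2 * n + 1, float(cmd))
        pieces.append(seg if not pieces else seg[1:])
        n_total += n
    v_cmd = np.concatenate(pieces)
    y = steady_state_vector(v_init, params)
    if not params.include_slow_inactivation:
        y[4] = 1.0
    n_rec = n_total // stride + 1
    out = np.empty((n_rec, 5))
    run_voltage_clamp(y, params.pack(), v_cmd, dt, stride, out)
    total = out[:, 1:].sum(axis=1) if leak_subtracted else out.sum(axis=1)
    t = np.arange(n_rec) * dt * stride
    cmd_rec = v_cmd[:: 2 * stride]
    return Trace(
        t=t,
        v=cmd_rec,
        command=cmd_rec,
        dt=dt * stride,
        i=total,
        currents=out,
        params=params.to_dict(),
        meta={"leak_subtracted": leak_subtracted},
    )


def vclamp_step_protocol(
    params: ModelParameters,
    vh: float = -100.0,
    prepulse: Tuple[float, float] = (-100.0, 300.0),
    steps: Sequence[float] = tuple(range(-60, 50, 10)),
    step_dur: float = 500.0,
    dt: float = 0.01,
    record_stride: int = 5,
    leak_subtracted: bool = True,
) -> List[Trace]:
    """Voltage steps after a conditioning prepulse (ideal clamp).

    Gates equilibrate at ``vh`` before the prepulse.  A prepulse at -30 mV
    inactivates IA (hA_inf(-30) ~ 0.003) and isolates IKdr; IA is the offline
    subtraction of IKdr from the total potassium current, which in-silico is
    exact by superposition.  Sodium currents are removed by zeroing GNat and
    GNap beforehand (TTX emulation), not here.
    """
    pre_v, pre_dur = prepulse
    traces = []
    for v_step in steps:
        tr = _vclamp_run(
            params,
            [(pre_dur, pre_v), (step_dur, float(v_step))],
            v_init=vh,
            dt=dt,
            stride=record_stride,
            leak_subtracted=leak_subtracted,
        )
        tr.meta["v_step"] = float(v_step)
        tr.meta["step_onset_ms"] = pre_dur
        traces.append(tr)
    return traces


def ramp_inap_protocol(
    params: ModelParameters,
    slope: float = 70.0,
    v_start: float = -100.0,
    v_stop: float = 0.0,
    dt: float = 0.01,
    record_stride: int = 5,
):
    """Slow depolarizing voltage ramp isolating INap by TTX subtraction.

    ``slope`` is in mV/s.  Returns (control trace, TTX trace, estimate dict)
    where the estimate holds the subtracted INap waveform, its (inward,
    negative) peak and the voltage at the peak.  The ramp is slow enough for
    mp to track its steady state while INat stays largely inactivated.
    """
    dur = (v_stop - v_start) / (slope / 1000.0)
    segs = [(dur, ("ramp", v_start, v_stop))]
    control = _vclamp_run(params, segs, v_start, dt, record_stride, True)
    ttx_params = apply_pharmacology(params, ttx=True)
    ttx = _vclamp_run(ttx_params, segs, v_start, dt, record_stride, True)
    inap = control.i - ttx.i
    k = int(np.argmin(inap))
    estimate = {
        "i_nap_pa": inap,
        "v_mv": control.v,
        "peak_pa": float(inap[k]),
        "v_at_peak_mv": float(control.v[k]),
    }
    return control, ttx, estimate


# ---------------------------------------------------------------------------
# Pharmacology as parameter scaling
# ---------------------------------------------------------------------------

_GIN_FACTOR_REF = (300.0, 0.77)  # 23% mean Gin decrease at 300 uM 4-AP
_GIN_LOG_FLOOR = 0.3             # lowest concentration probed, uM


def _gin_scale(conc: float) -> float:
    """Leak-conductance scaling under 4-AP: linear in log10 concentration
    from 1.0 at the lowest probed dose to the measured factor at 300 uM."""
    c_ref, f_ref = _GIN_FACTOR_REF
    if conc <= _GIN_LOG_FLOOR:
        return 1.0
    if conc >= c_ref:
        return f_ref
    frac = np.log10(conc / _GIN_LOG_FLOOR) / np.log10(c_ref / _GIN_LOG_FLOOR)
    return 1.0 + (f_ref - 1.0) * frac


def apply_pharmacology(
    params: ModelParameters,
    fourap_um: float = 0.0,
    ttx: bool = False,
    rheobase_matched: bool = False,
    dose_response=None,
) -> ModelParameters:
    """Emulate TTX and/or 4-AP as conductance scalings.

    TTX zeroes both sodium conductances.  4-AP scales GKdr by the remaining
    fraction of the Hill dose-response model (default: the fitted block of
    IKdr, IC50 = 2.9 uM) and scales Gin by an interpolated factor (23%
    decrease at 300 uM).  With ``rheobase_matched`` the injected current is
    rescaled proportionally to Gin, as done experimentally to keep the
    stimulus at a comparable multiple of rheobase.
    """
    if fourap_um < 0:
        raise ValueError("4-AP concentration must be >= 0")
    out = params
    if ttx:
        out = out.with_(gnat=0.0, gnap=0.0)
    if fourap_um > 0:
        from .population import DoseResponseModel, hill_inhibition

        model = dose_response or DoseResponseModel(imin=5.0, ic50=2.9, nh=1.0)
        kdr_frac = hill_inhibition(fourap_um, model) / 100.0
        gin_frac = _gin_scale(fourap_um)
        updates = {"gkdr": out.gkdr * kdr_frac, "gin": out.gin * gin_frac}
        if out.include_ia:
            updates["ga"] = out.ga  # 4-AP spares IA at these concentrations
        if rheobase_matched:
            updates["i"] = out.i * gin_frac
        out = out.with_(**updates)
    return out
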