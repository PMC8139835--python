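"""Channel-noise realization of the model with discrete Markov channels.

Each maximal conductance is converted into a finite channel population
(unitary conductance 10 pS), every channel carrying three independent
activation subunits and, for the sodium currents, an inactivation gate:
INat channels live on a 4x2 Markov chain (open m-subunits x h state), INap
channels on a 4x2 chain (mp x slow gate s, the latter frozen open without
slow inactivation), IKdr channels on a 4-state chain.  Per-gate opening and
closing rates are alpha = x_inf(V)/tau_x and beta = (1 - x_inf(V))/tau_x, so
the ensemble mean recovers the deterministic gating kinetics.

Simulation uses a hybrid Gillespie scheme: transition waiting times are
drawn exactly for rates frozen at the current voltage, and the membrane
equation — linear while the open-channel counts are constant — is advanced
by its exact exponential solution, with rates refreshed at least every
0.025 ms.  IA is not part of the stochastic model.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from . import _kernels
from .params import ModelParameters
from .phenotype import segment_up_down
from .protocols import Protocol, Trace, settle

__all__ = [
    "GAMMA_NS",
    "channel_counts",
    "gillespie_simulate",
    "stationary_occupancy",
    "stochastic_burst_statistics",
]

#: unitary channel conductance, nS (10 pS for all channels)
GAMMA_NS = 0.01

#: maximum interval between voltage/rate refreshes, ms
DT_MAX_MS = 0.025


def channel_counts(g: float, gamma: float = GAMMA_NS) -> int:
    """Number of discrete channels realizing maximal conductance ``g`` nS."""
    if g < 0:
        raise ValueError("conductance must be >= 0")
    return int(round(g / gamma))


def _init_populations(params: ModelParameters, v0: float, gamma: float):
    g = params.gates
    nat = np.zeros((4, 2), dtype=np.int64)
    nap = np.zeros((4, 2), dtype=np.int64)
    kdr4 = np.zeros((4, 2), dtype=np.int64)
    _kernels.init_channel_counts(
        channel_counts(params.gnat, gamma),
        float(g["m"].steady_state(v0)),
        float(g["h"].steady_state(v0)),
        nat,
    )
    p_s = (
        float(g["s"].steady_state(v0))
        if params.include_slow_inactivation
        else 1.0
    )
    _kernels.init_channel_counts(
        channel_counts(params.gnap, gamma),
        float(g["mp"].steady_state(v0)),
        p_s,
        nap,
    )
    _kernels.init_channel_counts(
        channel_counts(params.gkdr, gamma),
        float(g["n"].steady_state(v0)),
        1.0,
        kdr4,
    )
    kdr = kdr4.sum(axis=1)
    return nat, nap, kdr


def gillespie_simulate(
    params: ModelParameters,
    protocol: Protocol,
    seed: int,
    gamma: float = GAMMA_NS,
    rec_dt: float = 0.05,
    if_clamped_v: Optional[float] = None,
) -> Trace:
    """Stochastic counterpart of :func:`v1r.protocols.integrate`.

    Runs the current-clamp protocol with discrete channels; reproducible
    given ``seed``.  ``if_clamped_v`` freezes the voltage (stationarity
    checks).  The occupancy accumulators (time-averaged subunit open
    fractions m, h, mp, s, n) are reported in ``trace.meta['occupancy']``.
    """
    if params.include_ia:
        raise NotImplementedError("IA channels are not part of the stochastic model")
    if protocol.mode != "current_clamp":
        raise ValueError("gillespie_simulate expects a current-clamp protocol")
    _kernels.seed_rng(int(seed))
    y0 = settle(params, protocol.holding)
    v0 = float(if_clamped_v if if_clamped_v is not None else y0[0])
    clamp = if_clamped_v is not None
    nat, nap, kdr = _init_populations(params, v0, gamma)
    p = params.pack()
    t_parts: List[np.ndarray] = []
    v_parts: List[np.ndarray] = []
    c_parts: List[np.ndarray] = []
    occ = np.zeros(5)
    t0 = 0.0
    v = v0
    total_t = 0.0
    for dur, cmd in protocol.segments:
        n_rec = int(round(dur / rec_dt))
        out_v = np.empty(n_rec)
        v = _kernels.run_gillespie(
            p, gamma, float(cmd), float(dur), rec_dt, v,
            nat, nap, kdr, occ, out_v, clamp, DT_MAX_MS,
        )
        t_parts.append(t0 + np.arange(n_rec) * rec_dt)
        v_parts.append(out_v)
        c_parts.append(np.full(n_rec, float(cmd)))
        t0 += dur
        total_t += dur
    return Trace(
        t=np.concatenate(t_parts),
        v=np.concatenate(v_parts),
        command=np.concatenate(c_parts),
        dt=rec_dt,
        params=params.to_dict(),
        protocol=protocol.to_dict(),
        meta={
            "seed": int(seed),
            "gamma_ns": gamma,
            "occupancy": (occ / total_t).tolist(),
            "stochastic": True,
        },
    )


def stationary_occupancy(
    params: ModelParameters, v_clamp: float, duration: float, seed: int,
    gamma: float = GAMMA_NS,
) -> dict:
    """Time-averaged subunit open fractions at a clamped voltage.

    At stationarity each should match its deterministic steady state
    x_inf(V); used as a detailed-balance check of the Markov scheme.
    """
    proto = Protocol("current_clamp", ((duration, 0.0),), dt=0.01)
    tr = gillespie_simulate(
        params, proto, seed, gamma=gamma, if_clamped_v=v_clamp
    )
    m, h, mp, s, n = tr.meta["occupancy"]
    return {"m": m, "h": h, "mp": mp, "s": s, "n": n}


def stochastic_burst_statistics(
    params: ModelParameters,
    protocol: Protocol,
    n_seeds: int,
    base_seed: int = 0,
    gamma: float = GAMMA_NS,
    settle_ms: float = 1000.0,
) -> dict:
    """Distributions of plateau (up) and quiescent (down) durations under
    channel noise, for the slow-inactivation model.

    The first ``settle_ms`` of each realization is discarded along with the
    unfinished first/last segments; per-seed duration lists and pooled
    mean/CV summaries are returned.
    """
    if not params.include_slow_inactivation:
        raise ValueError("burst statistics require the slow-inactivation model")
    per_seed = []
    for k in range(n_seeds):
        tr = gillespie_simulate(params, protocol, base_seed + k, gamma=gamma)
        mask = tr.t >= settle_ms
        t, v = tr.t[mask], tr.v[mask]
        _, seg_up, seg_down = segment_up_down(t, v)
        ups = [t[b] - t[a] for a, b in seg_up[1:-1] if b > a]
        downs = [t[b] - t[a] for a, b in seg_down[1:-1] if b > a]
        per_seed.append({"seed": base_seed + k, "up_ms": ups, "down_ms": downs})
    pooled_up = np.concatenate([s["up_ms"] for s in per_seed]) if per_seed else np.array([])
    pooled_down = np.concatenate([s["down_ms"] for s in per_seed]) if per_seed else np.array([])

    def summary(x):
        if len(x) == 0:
            return {"mean_ms": np.nan, "cv": np.nan, "n": 0}
        return {
            "mean_ms": float(np.mean(x)),
            "cv": float(np.std(x) / np.mean(x)) if np.mean(x) > 0 else np.nan,
            "n": int(len(x)),
        }

    return {
        "per_seed": per_seed,
        "up": summary(pooled_up),
        "down": summary(pooled_down),
    }
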