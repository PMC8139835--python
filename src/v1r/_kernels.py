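"""Numba-compiled numeric kernels.

Parameter vectors follow the layout produced by ``ModelParameters.pack()``:

    0  cin   1  gin   2  vr    3  ena   4  ek
    5  gnat  6  gnap  7  gkdr  8  ga    9  i
    10 Vm    11 km    12 tau_m
    13 Vh    14 kh    15-18 tau_h coefs (a, b, c, d)
    19 Vmp   20 kmp   21 tau_mp
    22 Vs    23 ks    24 tau_s
    25 Vn    26 kn    27 tau_n
    28 VmA   29 kmA
    30 VhA   31 khA   32 tau_hA
    33 include_ia (0/1)   34 include_slow_inactivation (0/1)

State vectors are [V, m, h, mp, s, n, hA].
"""

import numpy as np
from numba import njit

__all__ = ["deriv", "run_current_clamp", "run_voltage_clamp", "run_gillespie"]


@njit(cache=True, inline="always")
def _sig(v, v_half, k):
    return 1.0 / (1.0 + np.exp(-(v - v_half) / k))


@njit(cache=True, inline="always")
def _tau_h(v, p):
    return p[15] - p[16] * np.tanh((v + p[17]) / p[18])


@njit(cache=True)
def deriv(y, p, i_ext):
    """Time derivative of the full state under injected current ``i_ext``."""
    v, m, h, mp, s, n, ha = y[0], y[1], y[2], y[3], y[4], y[5], y[6]
    ma_inf = _sig(v, p[28], p[29])
    i_ion = (
        p[1] * (p[2] - v)
        + p[5] * m * m * m * h * (p[3] - v)
        + p[6] * mp * mp * mp * s * (p[3] - v)
        + p[7] * n * n * n * (p[4] - v)
        + p[8] * ma_inf * ha * (p[4] - v)
    )
    out = np.empty(7)
    out[0] = (i_ion + i_ext) / p[0]
    out[1] = (_sig(v, p[10], p[11]) - m) / p[12]
    out[2] = (_sig(v, p[13], p[14]) - h) / _tau_h(v, p)
    out[3] = (_sig(v, p[19], p[20]) - mp) / p[21]
    out[4] = (_sig(v, p[22], p[23]) - s) / p[24] if p[34] > 0.5 else 0.0
    out[5] = (_sig(v, p[25], p[26]) - n) / p[27]
    out[6] = (_sig(v, p[30], p[31]) - ha) / p[32]
    return out


@njit(cache=True)
def run_current_clamp(y, p, i_ext, dt, n_steps, stride, out):
    """Fixed-step RK4 under constant injected current.

    ``y`` is updated in place; every ``stride``-th state (starting with the
    initial one) is written into ``out`` of shape (n_steps//stride + 1, 7).
    Returns 0 on success, 1 if the state became non-finite.
    """
    r = 0
    out[0] = y
    for step in range(n_steps):
        k1 = deriv(y, p, i_ext)
        k2 = deriv(y + 0.5 * dt * k1, p, i_ext)
        k3 = deriv(y + 0.5 * dt * k2, p, i_ext)
        k4 = deriv(y + dt * k3, p, i_ext)
        for j in range(7):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
        if not np.isfinite(y[0]):
            return 1
        if (step + 1) % stride == 0:
            r += 1
            out[r] = y
    return 0


@njit(cache=True)
def _gate_deriv(y, p, v):
    """Gate derivatives only, with V imposed (ideal voltage clamp)."""
    out = np.empty(7)
    out[0] = 0.0
    out[1] = (_sig(v, p[10], p[11]) - y[1]) / p[12]
    out[2] = (_sig(v, p[13], p[14]) - y[2]) / _tau_h(v, p)
    out[3] = (_sig(v, p[19], p[20]) - y[3]) / p[21]
    out[4] = (_sig(v, p[22], p[23]) - y[4]) / p[24] if p[34] > 0.5 else 0.0
    out[5] = (_sig(v, p[25], p[26]) - y[5]) / p[27]
    out[6] = (_sig(v, p[30], p[31]) - y[6]) / p[32]
    return out


@njit(cache=True)
def run_voltage_clamp(y, p, v_cmd, dt, stride, out):
    """Integrate gates under an imposed voltage waveform.

    ``v_cmd`` holds the command potential at half-step resolution: index 2*i
    is the potential at step i, 2*i+1 at the midpoint. Currents are recorded
    outward-positive: out rows are (Ileak, INat, INap, IKdr, IA) in pA, at
    ``stride`` spacing including the initial sample.
    """
    n_steps = (v_cmd.shape[0] - 1) // 2
    r = 0
    for step in range(n_steps + 1):
        v = v_cmd[2 * step]
        if step % stride == 0:
            ma_inf = _sig(v, p[28], p[29])
            out[r, 0] = p[1] * (v - p[2])
            out[r, 1] = p[5] * y[1] ** 3 * y[2] * (v - p[3])
            out[r, 2] = p[6] * y[3] ** 3 * y[4] * (v - p[3])
            out[r, 3] = p[7] * y[5] ** 3 * (v - p[4])
            out[r, 4] = p[8] * ma_inf * y[6] * (v - p[4])
            r += 1
        if step == n_steps:
            break
        vm = v_cmd[2 * step + 1]
        vn = v_cmd[2 * step + 2]
        k1 = _gate_deriv(y, p, v)
        k2 = _gate_deriv(y + 0.5 * dt * k1, p, vm)
        k3 = _gate_deriv(y + 0.5 * dt * k2, p, vm)
        k4 = _gate_deriv(y + dt * k3, p, vn)
        for j in range(1, 7):
            y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
    return 0


# ---------------------------------------------------------------------------
# Stochastic (hybrid Gillespie) kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _init_counts(n_chan, p_sub, p_inact, counts):
    """Fill a (4, 2) count array: (open subunits 0..3) x (inact closed/open)."""
    for i in range(4):
        counts[i, 0] = 0
        counts[i, 1] = 0
    for _ in range(n_chan):
        k = 0
        for _ in range(3):
            if np.random.random() < p_sub:
                k += 1
        j = 1 if np.random.random() < p_inact else 0
        counts[k, j] += 1


@njit(cache=True)
def run_gillespie(
    p, gamma, i_ext, t_total, rec_dt, v0,
    nat, nap, kdr, occ, out_v, clamp, dt_max,
):
    """Hybrid Gillespie simulation of discrete Markov channels.

    Channel populations (counts passed in and updated in place):
      * ``nat``: (4, 2) — INat channels, (open m-subunits, h closed/open)
      * ``nap``: (4, 2) — INap channels, (open mp-subunits, s closed/open);
        with slow inactivation disabled all channels sit in the s-open column
      * ``kdr``: (4,)  — IKdr channels, open n-subunits

    A channel conducts gamma (nS) iff all three activation subunits are open
    and its inactivation gate (if any) is open.  Transition rates are frozen
    between voltage updates; the membrane equation is then linear and is
    advanced by its exact exponential solution.  Voltage is refreshed at
    least every ``dt_max`` ms.  ``occ`` accumulates time-weighted subunit
    open fractions (m, h, mp, s, n) for stationarity checks; divide by
    ``t_total``.  Returns the final voltage.
    """
    slow = p[34] > 0.5
    n_nat = 0
    n_nap = 0
    n_kdr = 0
    for i in range(4):
        n_nat += nat[i, 0] + nat[i, 1]
        n_nap += nap[i, 0] + nap[i, 1]
        n_kdr += kdr[i]
    t = 0.0
    v = v0
    next_rec = 0.0
    r = 0
    while t < t_total:
        # rates at current voltage
        am = _sig(v, p[10], p[11]) / p[12]
        bm = 1.0 / p[12] - am
        th = _tau_h(v, p)
        ah = _sig(v, p[13], p[14]) / th
        bh = 1.0 / th - ah
        amp = _sig(v, p[19], p[20]) / p[21]
        bmp = 1.0 / p[21] - amp
        if slow:
            a_s = _sig(v, p[22], p[23]) / p[24]
            b_s = 1.0 / p[24] - a_s
        else:
            a_s = 0.0
            b_s = 0.0
        an = _sig(v, p[25], p[26]) / p[27]
        bn = 1.0 / p[27] - an
        # total propensity over all populations
        total = 0.0
        for i in range(4):
            for j in range(2):
                c = nat[i, j]
                total += c * ((3 - i) * am + i * bm + (ah if j == 0 else bh))
                c = nap[i, j]
                total += c * ((3 - i) * amp + i * bmp + (a_s if j == 0 else b_s))
            total += kdr[i] * ((3 - i) * an + i * bn)
        # waiting time
        if total > 0.0:
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            tau = -np.log(u) / total
        else:
            tau = t_total - t + 1.0
        step = tau if tau < dt_max else dt_max
        if t + step > t_total:
            step = t_total - t
            tau = step + 1.0
        # conducting conductances (frozen over the step)
        g_nat = gamma * nat[3, 1]
        g_nap = gamma * nap[3, 1]
        g_kdr = gamma * kdr[3]
        g_tot = p[1] + g_nat + g_nap + g_kdr
        v_ss = (p[1] * p[2] + (g_nat + g_nap) * p[3] + g_kdr * p[4] + i_ext) / g_tot
        tau_m = p[0] / g_tot
        # occupancy accumulation (subunit fractions, frozen over the step)
        if n_nat > 0:
            s_m = 0.0
            s_h = 0.0
            for i in range(4):
                s_m += i * (nat[i, 0] + nat[i, 1])
                s_h += nat[i, 1]
            occ[0] += step * s_m / (3.0 * n_nat)
            occ[1] += step * s_h / n_nat
        if n_nap > 0:
            s_mp = 0.0
            s_s = 0.0
            for i in range(4):
                s_mp += i * (nap[i, 0] + nap[i, 1])
                s_s += nap[i, 1]
            occ[2] += step * s_mp / (3.0 * n_nap)
            occ[3] += step * s_s / n_nap
        if n_kdr > 0:
            s_n = 0.0
            for i in range(4):
                s_n += i * kdr[i]
            occ[4] += step * s_n / (3.0 * n_kdr)
        # record and advance voltage along the exact exponential solution
        while next_rec <= t + step and r < out_v.shape[0]:
            if clamp:
                out_v[r] = v
            else:
                dt_r = next_rec - t
                out_v[r] = v_ss + (v - v_ss) * np.exp(-dt_r / tau_m)
            r += 1
            next_rec += rec_dt
        if not clamp:
            v = v_ss + (v - v_ss) * np.exp(-step / tau_m)
        t += step
        if tau > step:
            continue  # voltage-refresh step, no transition fired
        # pick and apply a transition
        x = np.random.random() * total
        done = False
        for i in range(4):
            for j in range(2):
                c = nat[i, j]
                a1 = c * (3 - i) * am
                a2 = c * i * bm
                a3 = c * (ah if j == 0 else bh)
                if x < a1:
                    nat[i, j] -= 1
                    nat[i + 1, j] += 1
                    done = True
                    break
                x -= a1
                if x < a2:
                    nat[i, j] -= 1
                    nat[i - 1, j] += 1
                    done = True
                    break
                x -= a2
                if x < a3:
                    nat[i, j] -= 1
                    nat[i, 1 - j] += 1
                    done = True
                    break
                x -= a3
            if done:
                break
        if done:
            continue
        for i in range(4):
            for j in range(2):
                c = nap[i, j]
                a1 = c * (3 - i) * amp
                a2 = c * i * bmp
                a3 = c * (a_s if j == 0 else b_s)
                if x < a1:
                    nap[i, j] -= 1
                    nap[i + 1, j] += 1
                    done = True
                    break
                x -= a1
                if x < a2:
                    nap[i, j] -= 1
                    nap[i - 1, j] += 1
                    done = True
                    break
                x -= a2
                if x < a3:
                    nap[i, j] -= 1
                    nap[i, 1 - j] += 1
                    done = True
                    break
                x -= a3
            if done:
                break
        if done:
            continue
        for i in range(4):
            a1 = kdr[i] * (3 - i) * an
            a2 = kdr[i] * i * bn
            if x < a1:
                kdr[i] -= 1
                kdr[i + 1] += 1
                done = True
                break
            x -= a1
            if x < a2:
                kdr[i] -= 1
                kdr[i - 1] += 1
                done = True
                break
            x -= a2
    return v


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def init_channel_counts(n_chan, p_sub, p_inact, counts):
    _init_counts(n_chan, p_sub, p_inact, counts)
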