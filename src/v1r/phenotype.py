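"""Firing-pattern phenotyping of simulated traces.

Events (action potentials or plateau potentials) evoked by a depolarizing
current pulse are detected as voltage excursions above a detection level set
10 mV above the pre-pulse baseline, and measured by their half-amplitude
duration (1/2Ad): the time spent above baseline + amplitude/2, where the
amplitude is the event's own peak relative to baseline.  Three descriptors
summarize a trace — mean 1/2Ad, its coefficient of variation (set to 0 when
the pulse evokes at most 3 spikes), and the depolarizing duration ratio
ddr = sum(1/2Ad)/Pw — and the pattern is classified as single spiking (SS),
repetitive spiking (RS), mixed events (ME) or plateau potential (PP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .protocols import Trace

__all__ = [
    "Event",
    "FiringFeatures",
    "detect_events",
    "compute_features",
    "classify_pattern",
    "phenotype_trace",
    "segment_up_down",
    "burst_structure",
    "PLATEAU_THRESHOLD_MS",
    "DETECTION_OFFSET_MV",
]

#: events with half-amplitude duration at or above this count as plateaus;
#: AP-like events in this preparation last ~10-25 ms at half amplitude,
#: plateaus hundreds of ms, so the gap is well over an order of magnitude
PLATEAU_THRESHOLD_MS = 100.0

#: detection level above baseline; channel-noise fluctuations can reach
#: ~5 mV, so 10 mV avoids false events
DETECTION_OFFSET_MV = 10.0

#: a plateau potential must depolarize beyond the regenerative (INap-driven)
#: voltage range; sustained passive depolarization during a current pulse
#: stays below this and is not an event
PLATEAU_MIN_PEAK_MV = -35.0

HYSTERESIS_MV = 5.0


@dataclass(frozen=True)
class Event:
    onset: float            # ms, first sample above the half-amplitude level
    offset: float           # ms, last sample above it
    peak: float             # mV
    half_amp_duration: float  # ms
    kind: str               # "AP" | "plateau"


@dataclass(frozen=True)
class FiringFeatures:
    mean_half_ad: float     # ms
    cv_half_ad: float       # percent
    ddr: float              # dimensionless, in [0, 1]
    n_events: int
    pattern: str            # "SS" | "RS" | "ME" | "PP" | "quiescent"


def detect_events(
    trace: Trace,
    pulse_window: Optional[Tuple[float, float]] = None,
    plateau_threshold: float = PLATEAU_THRESHOLD_MS,
    detection_offset: float = DETECTION_OFFSET_MV,
    plateau_min_peak: float = PLATEAU_MIN_PEAK_MV,
) -> List[Event]:
    """Detect evoked events within the pulse window of a current-step trace.

    The baseline is the mean voltage over the 100 ms preceding pulse onset.
    Each excursion above baseline + ``detection_offset`` yields one event
    whose half-amplitude duration is measured at baseline + amplitude/2
    (the region containing the peak); events are clipped to the pulse
    window.
    """
    if pulse_window is None:
        pulse_window = trace.pulse_window
    if pulse_window is None:
        raise ValueError("trace carries no pulse window metadata")
    t, v = trace.t, trace.v
    t0, t1 = pulse_window
    if t0 < t[0] or t1 > t[-1] + 1e-9:
        raise ValueError("pulse window lies outside the trace")
    base_mask = (t >= t0 - 100.0) & (t < t0)
    if not base_mask.any():
        raise ValueError("no pre-pulse samples available for the baseline")
    baseline = float(np.mean(v[base_mask]))
    level = baseline + detection_offset

    win = (t >= t0) & (t <= t1)
    tw, vw = t[win], v[win]
    dt = float(tw[1] - tw[0])

    def runs_above(x: np.ndarray, thr: float):
        above = x > thr
        if not above.any():
            return []
        edges = np.diff(above.astype(np.int8))
        starts = list(np.where(edges == 1)[0] + 1)
        ends = list(np.where(edges == -1)[0] + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(len(x))
        return list(zip(starts, ends))

    # Each excursion above the detection level sets a half-amplitude level
    # from its own peak; events are the runs above that level.  The stretches
    # left between those runs are re-scanned at their own (lower) peak so
    # that a plateau does not disappear under the overshoot of the action
    # potential that starts it.  Any long-lasting event must also reach the
    # regenerative voltage range (PLATEAU_MIN_PEAK_MV): sustained passive
    # depolarization during the pulse is not an event.
    events: List[Event] = []

    def scan(a: int, b: int, depth: int) -> None:
        peak = float(np.max(vw[a:b]))
        half = baseline + 0.5 * (peak - baseline)
        runs = runs_above(vw[a:b], half)
        if not runs:
            return
        for ra, rb in runs:
            ia, ib = a + ra, a + rb
            onset, offset = float(tw[ia]), float(tw[ib - 1])
            dur = min(offset - onset + dt, t1 - onset)  # clip at pulse end
            run_peak = float(np.max(vw[ia:ib]))
            long_event = dur >= plateau_threshold
            # a long event qualifies as regenerative only if it stays in the
            # plateau voltage range late in the run; damped subthreshold
            # ringing after an onset spike peaks early and then settles low
            late_max = float(np.max(vw[(ia + ib) // 2 : ib]))
            if long_event and late_max < plateau_min_peak:
                continue  # sustained subthreshold depolarization
            if depth > 0 and not long_event:
                continue  # sub-level scanning only recovers plateaus
            events.append(
                Event(
                    onset=onset,
                    offset=min(offset, t1),
                    peak=run_peak,
                    half_amp_duration=float(dur),
                    kind="plateau" if long_event else "AP",
                )
            )
        if depth < 2:
            gaps = []
            prev = a
            for ra, rb in runs:
                if a + ra > prev:
                    gaps.append((prev, a + ra))
                prev = a + rb
            if b > prev:
                gaps.append((prev, b))
            for ga, gb in gaps:
                if gb - ga > 1:
                    scan(ga, gb, depth + 1)

    for a, b in runs_above(vw, level):
        scan(a, b, 0)
    events.sort(key=lambda e: e.onset)
    return events


def compute_features(
    events: Sequence[Event], pw: float, pattern: Optional[str] = None
) -> FiringFeatures:
    """Summarize a pulse's events into the three firing-pattern descriptors.

    CV is population SD / mean * 100 and is forced to 0 when the pulse
    evoked at most 3 events.  ddr = sum(1/2Ad)/Pw, clipped to [0, 1].
    """
    if pw <= 0:
        raise ValueError("pulse duration must be positive")
    if not events:
        return FiringFeatures(np.nan, np.nan, 0.0, 0, "quiescent")
    durs = np.array([e.half_amp_duration for e in events])
    mean = float(np.mean(durs))
    cv = 0.0 if len(durs) <= 3 else float(np.std(durs) / mean * 100.0)
    ddr = min(float(np.sum(durs) / pw), 1.0)
    if pattern is None:
        pattern = classify_pattern(events)
    return FiringFeatures(mean, cv, ddr, len(events), pattern)


def classify_pattern(events: Sequence[Event]) -> str:
    """SS / RS / ME / PP from the detected event list.

    SS: 1-3 action potentials, no plateau.  RS: 4 or more APs, no plateau.
    PP: plateau events with no APs outside them (each plateau starts with a
    full-blown action potential, so an AP immediately preceding or inside a
    plateau belongs to it).  ME: at least one plateau plus 2 or more APs
    outside plateaus (spiking episodes alternating with plateaus).  An
    empty list maps to the "quiescent" sentinel, kept distinct from SS
    (recordings always used suprathreshold pulses).
    """
    if not events:
        return "quiescent"
    plateaus = [e for e in events if e.kind == "plateau"]
    aps = [e for e in events if e.kind == "AP"]
    if not plateaus:
        return "SS" if len(aps) <= 3 else "RS"
    # Each plateau is launched by a full-blown AP and rapidly decaying
    # spikelets riding its onset; absorb any AP chain that runs into a
    # plateau with short gaps.  Genuine spiking episodes between plateaus
    # have much longer inter-spike gaps and stay outside.
    grace = 30.0  # ms
    absorbed = set()
    ordered = sorted(events, key=lambda e: e.onset)
    for k, e in enumerate(ordered):
        if e.kind != "plateau":
            continue
        edge = e.onset
        for j in range(k - 1, -1, -1):
            prev = ordered[j]
            if prev.kind != "AP" or edge - prev.offset > grace:
                break
            absorbed.add(j)
            edge = prev.onset
    outside = [
        e for k, e in enumerate(ordered)
        if e.kind == "AP"
        and k not in absorbed
        and not any(p.onset <= e.onset <= p.offset for p in plateaus)
    ]
    return "ME" if len(outside) >= 2 else "PP"


def phenotype_trace(trace: Trace, **kwargs) -> FiringFeatures:
    """detect_events + compute_features on a current-step trace."""
    window = trace.pulse_window
    events = detect_events(trace, **kwargs)
    return compute_features(events, window[1] - window[0])


# ---------------------------------------------------------------------------
# Burst structure of the slow-inactivation model
# ---------------------------------------------------------------------------

def segment_up_down(
    t: np.ndarray,
    v: np.ndarray,
    up_fraction: float = 0.5,
    hysteresis: float = HYSTERESIS_MV,
) -> Tuple[np.ndarray, list, list]:
    """Hysteresis up/down-state segmentation of a voltage trace.

    The threshold sits at ``up_fraction`` of the observed voltage range with
    a symmetric hysteresis band.  Returns (boolean up-state mask, list of
    (start, end) index pairs for up segments, same for down segments).
    """
    vmid = np.min(v) + up_fraction * (np.max(v) - np.min(v))
    hi_th, lo_th = vmid + hysteresis / 2, vmid - hysteresis / 2
    up = np.zeros(len(v), dtype=bool)
    state = v[0] > vmid
    for k in range(len(v)):
        if state and v[k] < lo_th:
            state = False
        elif not state and v[k] > hi_th:
            state = True
        up[k] = state
    segments_up, segments_down = [], []
    k0 = 0
    for k in range(1, len(up) + 1):
        if k == len(up) or up[k] != up[k0]:
            (segments_up if up[k0] else segments_down).append((k0, k - 1))
            k0 = k
    return up, segments_up, segments_down


def burst_structure(
    trace: Trace,
    pulse_window: Optional[Tuple[float, float]] = None,
    up_fraction: float = 0.35,
) -> dict:
    """Up/down-state segmentation of a recurring-plateau (bursting) trace.

    States are segmented by hysteresis thresholding of V around the midpoint
    of the observed voltage range; within each state a phase label 1-4 is
    assigned from the sign of ds/dt: INap inactivates (s falls) during
    plateaus (phase 1) and de-inactivates (s rises) during quiescent
    episodes (phase 3), with fast transitions (2: plateau->quiescence,
    4: quiescence->plateau) in between.  Requires the slow-inactivation
    model (trace must carry gating states).
    """
    if trace.states is None:
        raise ValueError("burst_structure needs a trace with recorded states")
    t, v, s = trace.t, trace.v, trace.states[:, 4]
    if pulse_window is None:
        pulse_window = trace.pulse_window
    if pulse_window is not None:
        m = (t >= pulse_window[0]) & (t <= pulse_window[1])
        t, v, s = t[m], v[m], s[m]
    up, seg_up, seg_down = segment_up_down(t, v, up_fraction=up_fraction)
    plateaus, quiescents, phases = [], [], []
    for k0, k1 in seg_up:
        plateaus.append(t[k1] - t[k0])
        ds = s[k1] - s[k0]
        phases.append((float(t[k0]), float(t[k1]), 1 if ds < 0 else 4))
    for k0, k1 in seg_down:
        quiescents.append(t[k1] - t[k0])
        ds = s[k1] - s[k0]
        phases.append((float(t[k0]), float(t[k1]), 3 if ds > 0 else 2))
    phases.sort()
    return {
        "plateau_durations_ms": np.array(plateaus),
        "quiescent_durations_ms": np.array(quiescents),
        "phases": phases,
        "s": s,
        "t": t,
        "up": up,
    }
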