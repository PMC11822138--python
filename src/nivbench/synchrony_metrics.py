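"""Synchrony measurement pipeline on 50 Hz recordings.

Implements the bench's analysis chain: decimation to the 50 Hz acquisition
grid, breath-cycle segmentation from the recorded markers, trigger delay
(Td), inspiratory time in excess (Tiex), the ventilator pressure-time
products of the triggering and early-pressurization phases, and the
steady-state cycle selection with its 14-cycle instability rule.

Conventions (the figure markers a-d of the bench description):

* Td = time from effort onset (a) to the airway-pressure nadir (b); the
  nadir is searched within 0.5 s of the onset and Td is only defined for
  triggered cycles.
* Tiex = time from the end of the simulated neural inspiration (c) to the
  return of circuit flow to the end-expiratory baseline (d); negative for
  premature cycling, positive for delayed cycling.
* PTP areas relative to the end-expiratory pressure P_ee (mean airway
  pressure over the last 100 ms of the preceding expiration): area A is the
  sub-baseline integral from the effort onset to the first upward
  re-crossing of P_ee; areas B and C are the positive integrals up to
  300 ms and from 300 to 500 ms after the onset.  PTP_trig = A (<= 0),
  PTP300 = B - |A|, PTP500 = B + C - |A|.

All timings are quantized to the 20 ms resolution of the recording grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .virtual_bench import Event, WaveformRecord

__all__ = [
    "BreathCycle",
    "CycleMetrics",
    "SteadyStateSelection",
    "downsample_to_50hz",
    "segment_cycles",
    "compute_td",
    "compute_tiex",
    "compute_ptp",
    "cycle_metrics",
    "select_steady_state",
]

GRID = 0.02  # s; 50 Hz acquisition resolution
MAX_TRIGGER_DELAY = 0.5  # s; nadir/trigger search window after effort onset
BASELINE_WINDOW = 0.1  # s; late-expiration window for P_ee and baseline flow
FLOW_RETURN_TOL = 1.0  # L/min above baseline counted as "returned"


def _snap(t: float) -> float:
    return round(t / GRID) * GRID


@dataclass(frozen=True)
class BreathCycle:
    """One segmented breath: effort markers and ventilator markers (seconds).

    ``vent_press_start``/``vent_press_end`` are NaN when undefined (e.g.
    untriggered efforts).
    """

    effort_onset: float
    effort_end: float
    vent_press_start: float
    vent_press_end: float
    triggered: bool
    insufflation_time: float = math.nan

    def __post_init__(self) -> None:
        if not self.effort_onset < self.effort_end:
            raise ValueError("effort_onset must precede effort_end")


@dataclass(frozen=True)
class CycleMetrics:
    """Synchrony metrics of one steady-state cycle.

    ``ptp_trig`` is area A (cmH2O*s, <= 0 by convention); ``flagged`` marks
    cycles whose airway pressure never re-crossed baseline within 500 ms.
    """

    td: float
    tiex: float
    ptp_trig: float
    ptp300: float
    ptp500: float
    flagged: bool = False


@dataclass(frozen=True)
class SteadyStateSelection:
    """Result of the steady-state cycle selection before one leak change."""

    cycles: tuple[BreathCycle, ...]
    stable: bool

    def __post_init__(self) -> None:
        if self.stable and len(self.cycles) != 5:
            raise ValueError("a stable selection holds exactly 5 cycles")
        if not self.stable and self.cycles:
            raise ValueError("an unstable selection holds no cycles")


# --------------------------------------------------------------------------
# Resampling
# --------------------------------------------------------------------------

def downsample_to_50hz(record: WaveformRecord) -> WaveformRecord:
    """Decimate a record to the 50 Hz acquisition grid by sample picking.

    No anti-alias filter is applied: this emulates an acquisition system
    sampling instantaneous sensor values.  Event times are snapped to the
    nearest 20 ms grid point.  The input rate must be an integer multiple
    of 50 Hz.
    """
    ratio = record.sample_rate / 50.0
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError("input rate must be an integer multiple of 50 Hz")
    step = int(round(ratio))
    channels = {k: v[::step].copy() for k, v in record.channels.items()}
    events = [Event(_snap(e.t), e.type, e.payload) for e in record.events]
    return WaveformRecord(50.0, channels, events)


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------

def _efforts_from_pmus(record: WaveformRecord) -> list[tuple[float, float]]:
    """Derive (onset, end) effort pairs by thresholding the driver channel.

    Used for externally recorded waveforms without an event log: onset when
    pmus crosses below a small fraction of the running effort depth, end
    when it recovers to 90% of the depth (the exponential release crosses
    that level within one 20 ms sample of the true hold end).
    """
    pmus = record.channels["pmus"]
    t = record.time
    depth = float(-pmus.min())
    if depth <= 0:
        return []
    on_thr = -0.05 * depth
    active = pmus < on_thr
    edges = np.flatnonzero(np.diff(active.astype(int)))
    pairs: list[tuple[float, float]] = []
    onset = None
    for i in edges:
        if active[i + 1] and onset is None:
            onset = i + 1
        elif onset is not None and not active[i + 1]:
            seg = pmus[onset : i + 2]
            seg_depth = -seg.min()
            rel = np.flatnonzero(seg <= -0.9 * seg_depth)
            end_idx = onset + (rel[-1] if rel.size else len(seg) - 1)
            pairs.append((t[onset], t[end_idx]))
            onset = None
    return pairs


def _event_times(record: WaveformRecord, type_: str) -> list[float]:
    return [e.t for e in record.events if e.type == type_]


def segment_cycles(record: WaveformRecord) -> list[BreathCycle]:
    """Segment a 50 Hz record into breath cycles.

    Effort markers come from the event log when present, otherwise from
    thresholding the driver (pmus) channel.  For each effort: the cycle is
    *triggered* when a ventilator trigger occurred within 0.5 s of the
    onset; the pressurization start is the airway-pressure nadir in that
    window; the pressurization end is the first return of circuit flow to
    the end-expiratory baseline (+1 L/min) after peak flow.
    """
    if record.sample_rate != 50.0:
        raise ValueError("segment_cycles expects a 50 Hz record")
    fs = 50.0
    paw = record.channels["paw"]
    q = record.channels["q_circuit"]
    n = len(record)

    onsets = _event_times(record, "effort_onset")
    ends = _event_times(record, "effort_end")
    if onsets and ends:
        efforts = []
        for o in onsets:
            later = [e for e in ends if e > o + 1e-9]
            if later:
                efforts.append((_snap(o), _snap(later[0])))
    else:
        efforts = _efforts_from_pmus(record)
    if not efforts:
        raise ValueError("record shorter than one effort period")

    triggers = _event_times(record, "trigger")
    cycle_offs = _event_times(record, "cycle_off")

    nwin = int(round(BASELINE_WINDOW * fs))
    cycles: list[BreathCycle] = []
    for k, (onset, end) in enumerate(efforts):
        i_on = int(round(onset * fs))
        if i_on < nwin or i_on >= n:
            continue
        next_onset = efforts[k + 1][0] if k + 1 < len(efforts) else record.duration
        i_next = min(n, int(round(next_onset * fs)))

        trig = next(
            (tr for tr in triggers if onset - GRID - 1e-9 <= tr <= onset + MAX_TRIGGER_DELAY + 1e-9),
            None,
        )
        triggered = trig is not None

        if triggered:
            i_hi = min(n, i_on + int(round(MAX_TRIGGER_DELAY * fs)) + 1)
            nadir = i_on + int(np.argmin(paw[i_on:i_hi]))
            vps = nadir / fs
        else:
            vps = math.nan

        baseline = float(np.mean(q[i_on - nwin : i_on]))
        seg = q[i_on:i_next]
        if seg.size:
            ipk = i_on + int(np.argmax(seg))
            below = np.flatnonzero(q[ipk:i_next] <= baseline + FLOW_RETURN_TOL)
            vpe = (ipk + below[0]) / fs if below.size else math.nan
        else:  # pragma: no cover - degenerate tail
            vpe = math.nan

        ti = math.nan
        if triggered:
            off = next((co for co in cycle_offs if co > trig + 1e-9), None)
            if off is not None and off < next_onset + MAX_TRIGGER_DELAY:
                ti = _snap(off - trig)
            elif not math.isnan(vpe) and not math.isnan(vps):
                ti = _snap(vpe - vps)
        cycles.append(
            BreathCycle(onset, end, vps, vpe, triggered, ti)
        )
    return cycles


# --------------------------------------------------------------------------
# Per-cycle metrics
# --------------------------------------------------------------------------

def compute_td(cycle: BreathCycle) -> float:
    """Trigger delay: effort onset to airway-pressure nadir, seconds (>= 0)."""
    if not cycle.triggered or math.isnan(cycle.vent_press_start):
        raise ValueError("trigger delay is undefined for untriggered cycles")
    return max(0.0, _snap(cycle.vent_press_start - cycle.effort_onset))


def compute_tiex(cycle: BreathCycle) -> float:
    """Inspiratory time in excess: end of neural inspiration to end of
    ventilator pressurization, seconds (signed; negative = premature)."""
    if not cycle.triggered or math.isnan(cycle.vent_press_end):
        raise ValueError("Tiex is undefined for untriggered cycles")
    return _snap(cycle.vent_press_end - cycle.effort_end)


def compute_ptp(cycle: BreathCycle, record: WaveformRecord) -> tuple[float, float, float, bool]:
    """Pressure-time products (ptp_trig, ptp300, ptp500, flagged) in cmH2O*s.

    Trapezoidal integration on the 50 Hz grid of the airway-pressure
    deviation from the end-expiratory pressure P_ee.  ``flagged`` is True
    when the pressure never re-crossed P_ee within 500 ms of the effort
    onset (areas B and C are then zero).
    """
    if not cycle.triggered:
        raise ValueError("PTP is undefined for untriggered cycles")
    fs = record.sample_rate
    if fs != 50.0:
        raise ValueError("compute_ptp expects a 50 Hz record")
    paw = record.channels["paw"]
    i_on = int(round(cycle.effort_onset * fs))
    nwin = int(round(BASELINE_WINDOW * fs))
    if i_on < nwin or i_on + int(0.5 * fs) >= len(paw):
        raise ValueError("cycle too close to the record edge for PTP")
    p_ee = float(np.mean(paw[i_on - nwin : i_on]))
    dev = paw - p_ee
    dt = 1.0 / fs
    i_500 = i_on + int(round(0.5 * fs))
    i_300 = i_on + int(round(0.3 * fs))

    eps = 1e-9
    below = np.flatnonzero(dev[i_on : i_500 + 1] < -eps)
    if below.size == 0:
        a_area = 0.0
        i_recross = i_on
        flagged = False
    else:
        i_first = i_on + int(below[0])
        after = np.flatnonzero(dev[i_first : i_500 + 1] >= -eps)
        if after.size == 0:
            # never re-crossed baseline within 500 ms
            a_area = float(np.trapezoid(np.minimum(dev[i_on : i_500 + 1], 0.0), dx=dt))
            return a_area, 0.0, 0.0, True
        i_recross = i_first + int(after[0])
        a_area = float(np.trapezoid(np.minimum(dev[i_on : i_recross + 1], 0.0), dx=dt))
        flagged = False

    pos = np.maximum(dev, 0.0)
    b_area = 0.0
    if i_recross < i_300:
        b_area = float(np.trapezoid(pos[i_recross : i_300 + 1], dx=dt))
    c_area = float(np.trapezoid(pos[i_300 : i_500 + 1], dx=dt))
    ptp_trig = a_area
    ptp300 = b_area - abs(a_area)
    ptp500 = b_area + c_area - abs(a_area)
    return ptp_trig, ptp300, ptp500, flagged


def cycle_metrics(cycle: BreathCycle, record: WaveformRecord) -> CycleMetrics:
    """Td, Tiex and PTP metrics of one triggered cycle."""
    ptp_trig, ptp300, ptp500, flagged = compute_ptp(cycle, record)
    return CycleMetrics(
        td=compute_td(cycle),
        tiex=compute_tiex(cycle),
        ptp_trig=ptp_trig,
        ptp300=ptp300,
        ptp500=ptp500,
        flagged=flagged,
    )


# --------------------------------------------------------------------------
# Steady-state selection
# --------------------------------------------------------------------------

def select_steady_state(
    cycles: list[BreathCycle], leak_change_time: float
) -> SteadyStateSelection:
    """Select 5 consecutive triggered cycles before a leak change.

    Scans the 14 cycles immediately preceding ``leak_change_time``, newest
    window first; if no window of 5 consecutive triggered cycles exists the
    condition is deemed unstable.  Raises ValueError when fewer than 14
    cycles precede the change.
    """
    prior = [c for c in cycles if c.effort_onset < leak_change_time - 1e-9]
    if len(prior) < 14:
        raise ValueError("need at least 14 cycles before the leak change")
    last14 = prior[-14:]
    for start in range(9, -1, -1):  # newest 5-cycle window first
        window = last14[start : start + 5]
        if all(c.triggered for c in window):
            return SteadyStateSelection(tuple(window), True)
    return SteadyStateSelection((), False)
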