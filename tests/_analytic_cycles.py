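"""Piecewise-linear single-breath fixtures with closed-form marker times and
pressure-time-product areas.

Every breakpoint lies on the 20 ms acquisition grid, so trapezoidal
integration at 50 Hz is exact and the expected values can be computed by
plain triangle/rectangle arithmetic, independently of the code under test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nivbench.virtual_bench import Event, WaveformRecord

GRID = 0.02
FS = 50.0


@dataclass(frozen=True)
class AnalyticCycle:
    """Ground truth of one constructed breath (all times absolute, on grid)."""

    onset: float
    effort_end: float
    nadir_time: float  # = vent_press_start
    recross_time: float  # paw back at baseline after the trigger dip
    flow_return_time: float  # = vent_press_end
    td: float
    tiex: float
    ptp_trig: float
    ptp300: float
    ptp500: float
    record: WaveformRecord


def _interp(t, pts):
    """Piecewise-linear signal through (time, value) breakpoints."""
    xs, ys = zip(*pts)
    return np.interp(t, xs, ys)


def build_cycle(
    *,
    onset: float = 2.0,
    dip_depth: float = 2.0,
    dip_width: float = 0.10,
    nadir_frac_idx: int = 3,  # nadir grid index within the dip
    ps: float = 10.0,
    ramp: float = 0.06,  # pressurization ramp after the re-crossing
    neural_ti: float = 0.9,
    tiex: float = -0.16,
    baseline_paw: float = 5.0,
    baseline_flow: float = 0.0,
    peak_flow: float = 60.0,
    duration: float = 8.0,
) -> AnalyticCycle:
    """One synthetic breath; every argument is snapped to the 20 ms grid.

    paw: flat baseline, triangular dip of ``dip_depth`` over ``dip_width``
    starting at ``onset``, then a linear rise over ``ramp`` to a plateau
    ``ps`` above baseline, held until the pressurization end, then release.
    Circuit flow: flat baseline, linear rise to ``peak_flow`` during early
    insufflation, then linear decay reaching exactly baseline + 1 L/min at
    the pressurization end (the flow-return marker), continuing below.
    """
    snap = lambda x: round(round(x / GRID) * GRID, 10)  # noqa: E731
    onset = snap(onset)
    dip_width = max(2 * GRID, snap(dip_width))
    ramp = max(GRID, snap(ramp))
    neural_ti = snap(neural_ti)
    effort_end = onset + neural_ti
    recross = onset + dip_width
    if not 1 <= nadir_frac_idx < dip_width / GRID:
        raise ValueError("nadir index outside the dip")
    nadir_time = onset + nadir_frac_idx * GRID
    if recross + ramp > onset + 0.3 - 1e-9:
        raise ValueError("pressurization must reach the plateau before 300 ms")
    press_end = snap(effort_end + tiex)
    tiex = round(press_end - effort_end, 10)
    if press_end < onset + 0.5:
        raise ValueError("pressurization end must lie beyond 500 ms for area C")

    n = int(round(duration * FS))
    t = np.arange(n) / FS

    pb = baseline_paw
    paw_pts = [
        (0.0, pb),
        (onset, pb),
        (nadir_time, pb - dip_depth),
        (recross, pb),
        (recross + ramp, pb + ps),
        (press_end, pb + ps),
        (press_end + 0.3, pb),
        (duration, pb),
    ]
    paw = _interp(t, paw_pts)

    qb = baseline_flow
    trig = nadir_time  # ventilator trigger at the nadir
    rise_end = recross + ramp
    # linear decay from the peak hits qb + 1 exactly at press_end
    q_pts = [
        (0.0, qb),
        (trig, qb),
        (rise_end, qb + peak_flow),
        (press_end, qb + 1.0),
        (press_end + 0.2, qb - 20.0),
        (min(press_end + 1.2, duration - GRID), qb),
        (duration, qb),
    ]
    q = _interp(t, q_pts)

    pmus = np.zeros(n)
    i_on, i_end = int(round(onset * FS)), int(round(effort_end * FS))
    pmus[i_on:i_end] = -8.0

    channels = {
        "paw": paw,
        "q_circuit": q,
        "q_lung": q.copy(),
        "q_leak": np.zeros(n),
        "pmus": pmus,
        "volume": np.zeros(n),
        "vent_phase": ((t >= trig) & (t < press_end)).astype(float),
    }
    events = [
        Event(onset, "effort_onset"),
        Event(effort_end, "effort_end"),
        Event(trig, "trigger"),
        Event(press_end, "cycle_off"),
    ]

    # closed-form expected values (triangle / trapezoid / rectangle areas)
    td = round(nadir_time - onset, 10)
    a_area = -0.5 * dip_depth * dip_width
    b_area = 0.5 * ps * ramp + ps * ((onset + 0.3) - rise_end)
    c_area = ps * 0.2
    return AnalyticCycle(
        onset=onset,
        effort_end=effort_end,
        nadir_time=nadir_time,
        recross_time=recross,
        flow_return_time=press_end,
        td=td,
        tiex=tiex,
        ptp_trig=a_area,
        ptp300=b_area - abs(a_area),
        ptp500=b_area + c_area - abs(a_area),
        record=WaveformRecord(FS, channels, events),
    )


def random_cycle(rng: np.random.Generator) -> AnalyticCycle:
    """Randomized grid-aligned fixture drawn from a realistic range."""
    dip_w_idx = int(rng.integers(2, 8))  # 0.04 .. 0.14 s
    return build_cycle(
        onset=2.0,
        dip_depth=float(rng.uniform(0.5, 3.0)),
        dip_width=dip_w_idx * GRID,
        nadir_frac_idx=int(rng.integers(1, dip_w_idx)),
        ps=float(rng.choice([8.0, 10.0, 14.0])),
        ramp=int(rng.integers(2, 5)) * GRID,
        neural_ti=float(rng.choice([0.8, 0.9])),
        tiex=int(rng.integers(-10, 61)) * GRID,  # -0.2 .. +1.2 s
        baseline_paw=float(rng.uniform(4.0, 6.0)),
        baseline_flow=float(rng.choice([0.0, 9.0, 20.0])),
        peak_flow=float(rng.uniform(40.0, 80.0)),
    )
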