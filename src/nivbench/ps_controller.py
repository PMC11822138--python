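"""Pressure-support NIV controller of the simulated second ventilator.

Implements flow triggering with leak compensation, sloped pressurization,
expiratory-trigger cycling, PEEP and the 2 s maximum insufflation time.
Decisions are evaluated at the 50 Hz recording resolution on the *sensed*
airway pressure and circuit flow; the physics runs faster underneath.

The leak-compensation mechanism of the commercial NIV mode is unpublished;
here it is an orifice-coefficient tracker: during late exhalation the
patient flow is near zero, so the ratio ``q_circuit / sqrt(paw)`` estimates
the leak orifice coefficient.  The per-breath estimate is exponentially
smoothed, which deliberately leaves a transient mis-compensation window
after an abrupt leak change - the mechanism behind leak-induced
auto-triggering.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VentSettings",
    "ControllerState",
    "settings_for",
    "estimate_leak_baseline",
    "check_trigger",
    "check_cycle_off",
    "paw_command",
]

#: Per-mechanics second-ventilator settings: (pressurization_slope s,
#: expiratory_trigger_pct %).
_SETTINGS_BY_MECHANICS = {
    "normal": (0.15, 25.0),
    "obstructive": (0.10, 40.0),
    "restrictive": (0.10, 15.0),
}

#: Exponential smoothing weight of the per-breath leak estimate.
LEAK_SMOOTHING_ALPHA = 0.3

#: Exhalation-tail window used by the leak estimator, seconds.
LEAK_TAIL_WINDOW = 0.2

#: Maximum flow range (L/min) over the oldest half of the exhalation tail
#: for the tail to count as quiescent.  In a normally triggered breath only
#: the newest tail samples carry the effort ramp, so the oldest half is
#: flat; during auto-trigger storms the lung is still emptying throughout
#: the tail and the estimator falls back to a whole-breath flow balance.
QUIESCENT_FLOW_RANGE = 1.0


@dataclass(frozen=True)
class VentSettings:
    """NIV pressure-support settings of the second ventilator.

    ``pressurization_slope`` follows the convention that the commanded
    pressure reaches 90% of the step after ``pressurization_slope`` seconds.
    ``expiratory_trigger_pct`` is the percentage of peak inspiratory flow at
    which the flow-cycling comparator fires.
    """

    ps_level: float
    peep: float = 5.0
    flow_trigger: float = 1.5  # L/min
    pressurization_slope: float = 0.15  # s
    expiratory_trigger_pct: float = 25.0
    max_insufflation: float = 2.0  # s
    fio2: float = 0.21  # ignored by the mechanics

    def __post_init__(self) -> None:
        if self.ps_level < 0:
            raise ValueError("ps_level must be >= 0")
        if not (0.0 < self.expiratory_trigger_pct < 100.0):
            raise ValueError("expiratory_trigger_pct must be in (0, 100)")
        if self.pressurization_slope <= 0 or self.max_insufflation <= 0:
            raise ValueError("invalid settings")


def settings_for(mechanics_label: str, ps_level: float, **overrides) -> VentSettings:
    """Bench default settings for a mechanics preset at the given PS level."""
    slope, etp = _SETTINGS_BY_MECHANICS[mechanics_label]
    kwargs = dict(
        ps_level=ps_level, pressurization_slope=slope, expiratory_trigger_pct=etp
    )
    kwargs.update(overrides)
    return VentSettings(**kwargs)


@dataclass
class ControllerState:
    """Mutable controller state carried across 50 Hz decision frames."""

    phase: str = "exhalation"  # "exhalation" | "insufflation"
    t_phase: float = 0.0
    peak_insp_flow: float = 0.0
    leak_estimate_coeff: float = 0.0  # (L/min)/sqrt(cmH2O)
    paw_command: float = 0.0
    trigger_count: int = 0  # consecutive samples above the trigger threshold
    cycle_count: int = 0  # consecutive samples below the cycling threshold
    # (q_circuit_sensed, paw_sensed) over the last 200 ms of exhalation
    exhal_tail: deque = field(default_factory=lambda: deque(maxlen=10))
    # whole-breath accumulators (sums of sensed q_circuit and sqrt(paw) over
    # 50 Hz frames since the last trigger), for the flow-balance fallback
    acc_q: float = 0.0
    acc_sqrtp: float = 0.0


def estimate_leak_baseline(state: ControllerState, record_tail=None) -> float:
    """Per-breath update of the leak orifice-coefficient estimate.

    ``record_tail`` is an iterable of ``(q_circuit L/min, paw cmH2O)`` pairs
    covering the last >= 200 ms of exhalation; defaults to the tail buffer
    the controller maintains.  Samples with non-positive airway pressure are
    excluded.  Returns (and stores) the smoothed, non-negative coefficient.
    """
    tail = list(record_tail) if record_tail is not None else list(state.exhal_tail)
    ratios = [q / math.sqrt(p) for q, p in tail if p > 0.0]
    if ratios:
        est = float(np.median(ratios))
        coeff = (1.0 - LEAK_SMOOTHING_ALPHA) * state.leak_estimate_coeff
        coeff += LEAK_SMOOTHING_ALPHA * est
        state.leak_estimate_coeff = max(0.0, coeff)
    return state.leak_estimate_coeff


def update_leak_estimate(state: ControllerState, exhalation_duration: float) -> float:
    """Breath-boundary leak-coefficient update with storm fallback.

    When the exhalation that just ended contains a quiescent tail (the
    oldest half of the 200 ms tail is flat), the late-exhalation
    median-ratio estimate is used (:func:`estimate_leak_baseline`).  During
    auto-trigger storms the trigger fires while the lung is still emptying,
    the tail never shows the bare leak flow, and the update falls back to a
    whole-breath flow balance: over a complete breath the lung volume is
    (nearly) periodic, so ``sum(q_circuit) / sum(sqrt(paw))`` isolates the
    orifice coefficient.  Both paths share the same exponential smoothing;
    the whole-breath accumulators are reset afterwards.
    """
    tail = list(state.exhal_tail)
    old_half = [q for q, _ in tail[: len(tail) // 2]]
    quiescent = (
        len(tail) >= 10 and max(old_half) - min(old_half) <= QUIESCENT_FLOW_RANGE
    )
    if quiescent:
        coeff = estimate_leak_baseline(state)
    elif state.acc_sqrtp > 0.0:
        est = max(0.0, state.acc_q / state.acc_sqrtp)
        coeff = (1.0 - LEAK_SMOOTHING_ALPHA) * state.leak_estimate_coeff
        coeff += LEAK_SMOOTHING_ALPHA * est
        state.leak_estimate_coeff = max(0.0, coeff)
        coeff = state.leak_estimate_coeff
    else:  # pragma: no cover - no samples since last trigger
        coeff = state.leak_estimate_coeff
    state.acc_q = 0.0
    state.acc_sqrtp = 0.0
    return coeff


def _compensated_flow(state: ControllerState, paw: float, q_circuit: float) -> float:
    return q_circuit - state.leak_estimate_coeff * math.sqrt(max(paw, 0.0))


def check_trigger(
    state: ControllerState, sample: tuple[float, float], settings: VentSettings
) -> bool:
    """Flow-trigger comparator (used when sync inspiration detection is off).

    ``sample`` is ``(paw, q_circuit)`` sensed at 50 Hz.  Fires when the
    leak-compensated flow stays at or above the trigger threshold for two
    consecutive samples (debounce against single-sample chatter).
    """
    paw, q = sample
    if _compensated_flow(state, paw, q) >= settings.flow_trigger:
        state.trigger_count += 1
    else:
        state.trigger_count = 0
    return state.trigger_count >= 2


#: Cycling comparator guards: the flow criterion is armed only once a real
#: inspiration is underway (peak above twice the trigger threshold, and a
#: short refractory period), so that it cannot fire on the near-zero flows
#: of the very first insufflation samples.
CYCLE_REFRACTORY = 0.1  # s


def check_cycle_off(
    state: ControllerState, sample: tuple[float, float], settings: VentSettings
) -> bool:
    """Expiratory-trigger comparator plus the maximum-insufflation cap.

    Fires when the compensated inspiratory flow falls to the set percentage
    of its peak for two consecutive samples, or unconditionally when the
    insufflation reaches ``settings.max_insufflation`` (2 s by default).
    """
    if state.t_phase >= settings.max_insufflation - 1e-9:
        return True
    paw, q = sample
    comp = _compensated_flow(state, paw, q)
    armed = (
        state.t_phase >= CYCLE_REFRACTORY
        and state.peak_insp_flow >= 2.0 * settings.flow_trigger
    )
    threshold = settings.expiratory_trigger_pct / 100.0 * state.peak_insp_flow
    if armed and comp <= threshold:
        state.cycle_count += 1
    else:
        state.cycle_count = 0
    return state.cycle_count >= 2


def paw_command(state: ControllerState, settings: VentSettings, dt: float) -> float:
    """Advance the commanded pressure one step toward the phase target.

    The target is ``peep + ps_level`` during insufflation and ``peep``
    during exhalation; the approach is exponential, reaching 90% of the
    step after ``pressurization_slope`` seconds.
    """
    target = (
        settings.peep + settings.ps_level
        if state.phase == "insufflation"
        else settings.peep
    )
    k = 1.0 - math.exp(-dt * math.log(10.0) / settings.pressurization_slope)
    state.paw_command += (target - state.paw_command) * k
    return state.paw_command
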