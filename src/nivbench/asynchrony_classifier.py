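"""Classification of classical patient-ventilator asynchronies and the
asynchrony index (AI).

Events are counted over windows spanning exactly 10 driver (effort) cycles,
taken immediately before (steady state) or after (post-modification) each
leak change:

* auto-triggering - a ventilator cycle whose trigger has no concurrent
  driver inspiratory phase;
* ineffective effort - a driver effort during which no ventilator cycle is
  triggered;
* double-triggering - two ventilator cycles separated by an expiratory time
  shorter than half the mean ventilator insufflation time, the second not
  effort-driven;
* late / early cycling - insufflation longer than twice / shorter than half
  the mean neural inspiratory time (the driver pressurization-phase time).

AI(type) = 100 * count(type) / (triggered ventilator cycles + ineffective
efforts).  A ventilator cycle can carry at most one of {late, early} plus at
most one of {auto, double}; ineffective efforts attach to efforts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .virtual_bench import WaveformRecord

__all__ = [
    "AsynchronyCounts",
    "AIResult",
    "classify_window",
    "asynchrony_index",
    "extract_window",
]

ASYNCHRONY_TYPES = (
    "auto_triggering",
    "ineffective_effort",
    "double_triggering",
    "late_cycling",
    "early_cycling",
)

#: Tolerance (s) on "concurrent with the driver inspiratory phase":
#: one 50 Hz sample.
PHASE_TOL = 0.02


@dataclass(frozen=True)
class AsynchronyCounts:
    auto_triggering: int = 0
    ineffective_effort: int = 0
    double_triggering: int = 0
    late_cycling: int = 0
    early_cycling: int = 0
    triggered_cycles: int = 0
    window: str = "steady_state"  # or "post_modification"

    def __post_init__(self) -> None:
        for name in ASYNCHRONY_TYPES + ("triggered_cycles",):
            if getattr(self, name) < 0:
                raise ValueError("counts must be non-negative")

    @property
    def total_events(self) -> int:
        return sum(getattr(self, name) for name in ASYNCHRONY_TYPES)


@dataclass(frozen=True)
class AIResult:
    per_type: dict
    total: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.total):
            raise ValueError("AI must be non-negative")


def _effort_driven(trig: float, efforts) -> bool:
    return any(o - PHASE_TOL <= trig <= e + PHASE_TOL for o, e in efforts)


def classify_window(
    efforts,
    vent_cycles,
    mean_neural_ti: float | None = None,
    window: str = "steady_state",
) -> AsynchronyCounts:
    """Count classical asynchronies over a 10-driver-cycle span.

    ``efforts`` is a sequence of exactly 10 ``(onset, end)`` driver-cycle
    intervals; ``vent_cycles`` the ``(trigger, cycle_off)`` intervals of all
    ventilator cycles in the same span.  ``mean_neural_ti`` defaults to the
    mean driver inspiratory (pressurization-phase) time of the window.
    """
    efforts = [(float(o), float(e)) for o, e in efforts]
    if len(efforts) != 10:
        raise ValueError("the classification span must hold exactly 10 driver cycles")
    vent_cycles = sorted((float(a), float(b)) for a, b in vent_cycles)
    if mean_neural_ti is None:
        mean_neural_ti = float(np.mean([e - o for o, e in efforts]))
    if mean_neural_ti <= 0:
        raise ValueError("mean neural inspiratory time must be positive")

    insufflations = [b - a for a, b in vent_cycles]
    mean_ti_vent = float(np.mean(insufflations)) if insufflations else 0.0

    double_idx: set[int] = set()
    for i in range(1, len(vent_cycles)):
        trig, _ = vent_cycles[i]
        prev_off = vent_cycles[i - 1][1]
        expiratory = trig - prev_off
        if (
            mean_ti_vent > 0
            and expiratory < 0.5 * mean_ti_vent
            and not _effort_driven(trig, efforts)
        ):
            double_idx.add(i)

    auto = double = late = early = 0
    for i, (trig, off) in enumerate(vent_cycles):
        if i in double_idx:
            double += 1
        elif not _effort_driven(trig, efforts):
            auto += 1
        ti = off - trig
        if ti > 2.0 * mean_neural_ti:
            late += 1
        elif ti < 0.5 * mean_neural_ti:
            early += 1

    ineffective = sum(
        1
        for o, e in efforts
        if not any(o - PHASE_TOL <= trig <= e + PHASE_TOL for trig, _ in vent_cycles)
    )

    return AsynchronyCounts(
        auto_triggering=auto,
        ineffective_effort=ineffective,
        double_triggering=double,
        late_cycling=late,
        early_cycling=early,
        triggered_cycles=len(vent_cycles),
        window=window,
    )


def asynchrony_index(counts: AsynchronyCounts) -> AIResult:
    """Asynchrony index: events as a percentage of the total respiratory
    rate (triggered ventilator cycles plus ineffective efforts).

    Raises ValueError on a zero denominator.
    """
    denom = counts.triggered_cycles + counts.ineffective_effort
    if denom <= 0:
        raise ValueError("asynchrony index undefined: zero denominator")
    per_type = {
        name: 100.0 * getattr(counts, name) / denom for name in ASYNCHRONY_TYPES
    }
    return AIResult(per_type=per_type, total=sum(per_type.values()))


# --------------------------------------------------------------------------
# Window extraction from simulated records
# --------------------------------------------------------------------------

def extract_window(record: WaveformRecord, t_change: float, which: str):
    """Pull the 10-driver-cycle span before or after a leak change.

    Returns ``(efforts, vent_cycles)`` suitable for :func:`classify_window`,
    or None when fewer than 10 complete driver cycles are available on the
    requested side.  ``which`` is ``"steady_state"`` (the 10 cycles ending
    before ``t_change``) or ``"post_modification"`` (the 10 starting after).
    """
    onsets = sorted(e.t for e in record.events if e.type == "effort_onset")
    ends = sorted(e.t for e in record.events if e.type == "effort_end")
    efforts = []
    for o in onsets:
        later = [e for e in ends if e > o + 1e-9]
        if later:
            efforts.append((o, later[0]))

    if which == "steady_state":
        sel = [p for p in efforts if p[1] < t_change]
        sel = sel[-10:]
    elif which == "post_modification":
        sel = [p for p in efforts if p[0] >= t_change]
        sel = sel[:10]
    else:
        raise ValueError("which must be 'steady_state' or 'post_modification'")
    if len(sel) < 10:
        return None

    period = (sel[-1][0] - sel[0][0]) / 9.0
    span_lo = sel[0][0] - PHASE_TOL
    span_hi = sel[-1][0] + period

    triggers = sorted(e.t for e in record.events if e.type == "trigger")
    offs = sorted(e.t for e in record.events if e.type == "cycle_off")
    vent_cycles = []
    for trig in triggers:
        if span_lo <= trig < span_hi:
            off = next((c for c in offs if c > trig + 1e-9), None)
            if off is not None:
                vent_cycles.append((trig, off))
    return sel, vent_cycles
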