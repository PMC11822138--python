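"""Virtual NIV bench: test lung, simulated inspiratory effort, calibrated leaks.

This module is the synthetic-data source of the package.  It emulates a
bench in which a driver produces a spontaneous inspiratory effort against a
single-compartment test lung, while a second ventilator delivers
pressure-support NIV through a leaky circuit.  The physical bench it mimics
drives the lung with a separate ventilator; here the effort is modelled
directly as a muscle-pressure source Pmus(t) whose intensity is calibrated
to standard occlusion indices (P0.1 and the global occlusion pressure).

Model summary
-------------
Single-compartment equation of motion at the airway node::

    q_lung = (paw - pmus - V/C) / R            [L/s]

with compliance C (L/cmH2O) and resistance R (cmH2O/(L/s)).  The ventilator
is a first-order pressure source behind a small fixed circuit resistance
``R_circ``; a calibrated orifice leak sits at the airway node, so flow
conservation reads ``q_circuit = q_lung + q_leak`` at every sample.
Integration is semi-implicit at >= 400 Hz; controller decisions and
recordings run at 50 Hz (20 ms resolution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "RespiratoryMechanics",
    "EffortProfile",
    "LeakSpec",
    "ProtocolSpec",
    "Event",
    "NoiseSpec",
    "WaveformRecord",
    "MECHANICS_PRESETS",
    "EFFORT_TIMING",
    "mechanics_preset",
    "effort_profile_for",
    "generate_pmus",
    "occlusion_test",
    "calibrate_effort",
    "leak_flow",
    "calibrate_leak",
    "step_lung",
    "simulate_condition",
    "run_protocol",
    "CIRCUIT_RESISTANCE",
    "INTERNAL_RATE",
    "DECISION_RATE",
]

#: Fixed resistance of the ventilator circuit between the pressure source and
#: the airway node, cmH2O/(L/s).  It is what lets a patient effort pull the
#: airway pressure below PEEP before the ventilator pressurizes (the nadir
#: used for trigger-delay measurement) and produces the sub-baseline
#: pressure-time-product trigger area.
CIRCUIT_RESISTANCE = 2.0

#: Internal physics rate (Hz) and controller/recording decision rate (Hz).
INTERNAL_RATE = 500
DECISION_RATE = 50


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RespiratoryMechanics:
    """One of the three lung models of the bench.

    compliance is in L/cmH2O, resistance in cmH2O/(L/s).  The passive time
    constant of the lung alone is ``tau = resistance * compliance``.
    """

    label: str
    compliance: float
    resistance: float

    def __post_init__(self) -> None:
        if not (self.compliance > 0 and self.resistance > 0):
            raise ValueError("compliance and resistance must be positive")

    @property
    def tau(self) -> float:
        return self.resistance * self.compliance


#: Central bench values: normal, obstructive, restrictive.
MECHANICS_PRESETS: dict[str, RespiratoryMechanics] = {
    "normal": RespiratoryMechanics("normal", 0.0783, 7.0),
    "obstructive": RespiratoryMechanics("obstructive", 0.0814, 24.6),
    "restrictive": RespiratoryMechanics("restrictive", 0.0494, 7.0),
}

#: Driver timing per mechanics: (hold_time, period) in seconds.  hold_time is
#: the driver high-pressure (neural inspiratory) time; period = hold + low
#: time, giving set rates of ~18, 14 and ~19 cycles/min.
EFFORT_TIMING: dict[str, tuple[float, float]] = {
    "normal": (0.9, 0.9 + 2.4),
    "obstructive": (0.9, 0.9 + 3.4),
    "restrictive": (0.8, 0.8 + 2.4),
}


def mechanics_preset(label: str) -> RespiratoryMechanics:
    try:
        return MECHANICS_PRESETS[label]
    except KeyError:
        raise KeyError(
            f"unknown mechanics preset {label!r}; expected one of "
            f"{sorted(MECHANICS_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class EffortProfile:
    """Periodic muscle-pressure waveform of the simulated effort.

    The waveform is, within each period: a linear ramp from 0 to
    ``-amplitude`` over ``rise_time``, a hold at ``-amplitude`` until
    ``hold_time`` after onset, then an exponential return to 0 with time
    constant ``relax_tau``.  All times in seconds, amplitude in cmH2O
    (stored positive; the generated pressure is negative).
    """

    amplitude: float
    rise_time: float = 0.2
    hold_time: float = 0.9
    relax_tau: float = 0.1
    period: float = 3.3

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0 < self.rise_time <= self.hold_time):
            raise ValueError("need 0 < rise_time <= hold_time")
        if not (self.period > self.hold_time):
            raise ValueError("period must exceed hold_time")
        if self.relax_tau <= 0:
            raise ValueError("relax_tau must be positive")

    @property
    def rate(self) -> float:
        """Implied respiratory rate, cycles/min."""
        return 60.0 / self.period


@dataclass(frozen=True)
class LeakSpec:
    """A calibrated orifice leak in the ventilator circuit.

    ``kind`` selects when the orifice is open: an inspiro-expiratory leak
    flows whenever airway pressure is positive; an inspiration-only leak
    flows only during ventilator insufflation.  ``orifice_coefficient`` is
    in (L/min)/sqrt(cmH2O); zero encodes the no-leak condition L0.
    """

    kind: str  # "inspiro-expiratory" | "inspiratory-only"
    level: str  # "L0" | "L9" | "L20"
    target_flow: float  # L/min
    orifice_coefficient: float

    _KINDS = ("inspiro-expiratory", "inspiratory-only")
    _LEVELS = {"L0": 0.0, "L9": 9.0, "L20": 20.0}

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.level not in self._LEVELS:
            raise ValueError("level must be L0, L9 or L20")
        if self._LEVELS[self.level] != self.target_flow:
            raise ValueError("target_flow inconsistent with level")
        if self.level == "L0" and self.orifice_coefficient != 0.0:
            raise ValueError("L0 requires a zero orifice coefficient")
        if self.orifice_coefficient < 0:
            raise ValueError("orifice_coefficient must be >= 0")

    @classmethod
    def no_leak(cls, kind: str = "inspiro-expiratory") -> "LeakSpec":
        return cls(kind, "L0", 0.0, 0.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """The leak-change protocol of one recorded condition.

    Defaults are the bench protocol: 15 baseline no-leak cycles, then the
    leak sequence L0->L9->L20->L9->L0->L20->L0 with a change every 120 s,
    preceded by a 300 s stabilization period that is simulated but not
    recorded.
    """

    baseline_cycles: int = 15
    leak_sequence: tuple[str, ...] = ("L0", "L9", "L20", "L9", "L0", "L20", "L0")
    step_duration: float = 120.0
    stabilization_before_recording: float = 300.0

    def __post_init__(self) -> None:
        if self.baseline_cycles < 0 or self.step_duration <= 0:
            raise ValueError("invalid protocol")
        if self.stabilization_before_recording < 0:
            raise ValueError("invalid stabilization time")


@dataclass(frozen=True)
class Event:
    """Timestamped simulation event (effort_onset, trigger, leak_change, ...)."""

    t: float
    type: str
    payload: dict = field(default_factory=dict)


@dataclass(frozen=True)
class NoiseSpec:
    """Zero-mean Gaussian sensor noise applied to what the controller and the
    synchronization detectors *sense* at 50 Hz.  Recorded channels stay
    noise-free so that flow conservation holds exactly on every record."""

    sigma_flow: float = 0.2  # L/min
    sigma_paw: float = 0.1  # cmH2O


@dataclass
class WaveformRecord:
    """Multichannel time-aligned recording of one simulated condition.

    Channels (all numpy arrays of equal length): ``paw`` (cmH2O at the
    airway node), ``q_circuit``/``q_lung``/``q_leak`` (L/min), ``pmus``
    (cmH2O), ``volume`` (L above the relaxation volume), ``vent_phase``
    (0 = exhalation, 1 = insufflation).
    """

    sample_rate: float
    channels: dict[str, np.ndarray]
    events: list[Event] = field(default_factory=list)

    CHANNEL_NAMES = ("paw", "q_circuit", "q_lung", "q_leak", "pmus", "volume", "vent_phase")

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")

    def __len__(self) -> int:
        return len(self.channels["paw"])

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self) / self.sample_rate

    def events_of(self, *types: str) -> list[Event]:
        return [e for e in self.events if e.type in types]


# --------------------------------------------------------------------------
# Effort generation and occlusion calibration
# --------------------------------------------------------------------------

def generate_pmus(profile: EffortProfile, t):
    """Muscle pressure (cmH2O, <= 0) of the simulated effort at time ``t``.

    Total function of t >= 0; accepts scalars or arrays.  The first effort
    onset is at t = 0 and the waveform repeats with ``profile.period``.
    """
    t = np.asarray(t, dtype=float)
    a = profile.amplitude
    if a == 0.0:
        return np.zeros_like(t) if t.ndim else 0.0
    phase = np.mod(t, profile.period)
    ramp = -a * phase / profile.rise_time
    hold = np.full_like(phase, -a)
    relax = -a * np.exp(-(phase - profile.hold_time) / profile.relax_tau)
    out = np.where(
        phase < profile.rise_time, ramp, np.where(phase < profile.hold_time, hold, relax)
    )
    return out if out.ndim else float(out)


def occlusion_test(
    profile: EffortProfile, n_efforts: int = 10, dt: float = 1.0 / INTERNAL_RATE
) -> tuple[float, float]:
    """Simulated airway-occlusion maneuver: (P0.1, Poccl), both in cmH2O.

    Airway flow is clamped to zero, so with constant lung volume the airway
    pressure deflection from baseline equals the muscle pressure.  P0.1 is
    the deflection exactly 100 ms after effort onset, Poccl the maximal
    deflection during the effort; both are averaged over ``n_efforts``
    simulated efforts.
    """
    if n_efforts < 1:
        raise ValueError("need at least one simulated effort")
    p01s, pocls = [], []
    n_per = int(round(profile.period / dt))
    i_100ms = int(round(0.1 / dt))
    for k in range(n_efforts):
        t = (k * n_per + np.arange(n_per)) * dt
        deflection = np.asarray(generate_pmus(profile, t))
        p01s.append(deflection[i_100ms])
        pocls.append(deflection.min())
    return float(np.mean(p01s)), float(np.mean(pocls))


def calibrate_effort(
    target_p01: float = -5.58,
    target_poccl: float = -13.48,
    mechanics_label: str = "normal",
    relax_tau: float = 0.1,
) -> EffortProfile:
    """Effort profile whose occlusion indices match the stated targets.

    The hold time and period are fixed by the driver settings of the chosen
    mechanics; the amplitude equals |Poccl| (under occlusion the plateau
    deflection is the full muscle pressure) and the linear ramp is sized so
    that it passes through ``target_p01`` at 100 ms.

    Raises ValueError for infeasible targets (|P0.1| >= |Poccl|, or a ramp
    longer than the hold time).
    """
    if not (target_p01 < 0 and target_poccl < 0):
        raise ValueError("occlusion targets must be negative pressures")
    if abs(target_p01) >= abs(target_poccl):
        raise ValueError(
            "infeasible targets: a finite-slope ramp cannot make |P0.1| reach "
            "|Poccl| within 100 ms"
        )
    amplitude = -target_poccl
    rise_time = 0.1 * amplitude / (-target_p01)
    hold, period = EFFORT_TIMING[mechanics_label]
    if rise_time > hold:
        raise ValueError("infeasible targets: required ramp exceeds the hold time")
    profile = EffortProfile(
        amplitude=amplitude,
        rise_time=rise_time,
        hold_time=hold,
        relax_tau=relax_tau,
        period=period,
    )
    p01, poccl = occlusion_test(profile)
    if abs(p01 - target_p01) > 0.02 * abs(target_p01) or abs(
        poccl - target_poccl
    ) > 0.02 * abs(target_poccl):  # pragma: no cover - defensive
        raise RuntimeError("effort calibration failed to verify within 2%")
    return profile


def effort_profile_for(label: str, calibrated: EffortProfile) -> EffortProfile:
    """Re-time a calibrated effort for another mechanics preset.

    A single effort amplitude is used across mechanics; only hold time and
    period follow the driver settings of the preset.
    """
    hold, period = EFFORT_TIMING[label]
    return replace(calibrated, hold_time=hold, period=period)


# --------------------------------------------------------------------------
# Leak model
# --------------------------------------------------------------------------

def leak_flow(paw: float, spec: LeakSpec, insufflation: bool) -> float:
    """Instantaneous orifice leak flow in L/min.

    Turbulent-orifice law ``q = k * sign(paw) * sqrt(|paw|)``.  An
    inspiration-only leak is closed outside ventilator insufflation.
    """
    k = spec.orifice_coefficient
    if k == 0.0:
        return 0.0
    if spec.kind == "inspiratory-only" and not insufflation:
        return 0.0
    return k * math.copysign(math.sqrt(abs(paw)), paw)


# --------------------------------------------------------------------------
# Lung integration step
# --------------------------------------------------------------------------

def step_lung(
    state: tuple[float, float],
    paw: float,
    pmus: float,
    mechanics: RespiratoryMechanics,
    dt: float,
) -> tuple[float, float]:
    """One semi-implicit integration step of the single-compartment lung.

    ``state`` is ``(volume_L, q_lung_Ls)``; returns the updated state given
    the airway pressure (cmH2O) applied over ``dt`` seconds.  The passive
    decay time constant equals ``mechanics.tau``.
    """
    if dt > 2.5e-3:
        raise ValueError("dt must be <= 2.5 ms (internal rate >= 400 Hz)")
    volume, _ = state
    if not (math.isfinite(volume) and math.isfinite(paw) and math.isfinite(pmus)):
        raise FloatingPointError("non-finite lung state")
    r, c = mechanics.resistance, mechanics.compliance
    # implicit in the elastic term: V' = (paw - pmus - V/C)/R
    q = (paw - pmus - volume / c) / (r + dt / c)
    return volume + dt * q, q


# --------------------------------------------------------------------------
# Closed-loop simulation engine
# --------------------------------------------------------------------------

def _leak_schedule_from_protocol(
    protocol: ProtocolSpec,
    specs: dict[str, LeakSpec],
    effort_period: float,
) -> tuple[list[tuple[float, LeakSpec]], float]:
    """Expand a ProtocolSpec into (start_time, LeakSpec) steps (times relative
    to the start of the recording) and the total recorded duration."""
    baseline = protocol.baseline_cycles * effort_period
    schedule: list[tuple[float, LeakSpec]] = [(0.0, specs["L0"])]
    t = baseline
    for level in protocol.leak_sequence:
        schedule.append((t, specs[level]))
        t += protocol.step_duration
    return schedule, t


def simulate_condition(
    mechanics: RespiratoryMechanics,
    effort: EffortProfile,
    settings,
    leak: "LeakSpec | Sequence[tuple[float, LeakSpec]]",
    sync_mode: str = "IS0",
    duration: float = 60.0,
    *,
    detector_cfg=None,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
    record_from: float = 0.0,
    internal_rate: int = INTERNAL_RATE,
) -> WaveformRecord:
    """Closed-loop simulation of one condition; returns a WaveformRecord.

    ``leak`` is either a single LeakSpec held for the whole run or a
    schedule of ``(start_time, LeakSpec)`` steps (times relative to the start
    of the *recording*).  ``record_from`` seconds are simulated first and
    discarded (stabilization).  The record is sampled at ``internal_rate``;
    use :func:`nivbench.synchrony_metrics.downsample_to_50hz` for analysis
    at the bench acquisition rate.
    """
    from . import ps_controller as psc
    from . import waveform_sync as ws

    if internal_rate % DECISION_RATE != 0:
        raise ValueError("internal rate must be a multiple of 50 Hz")
    if isinstance(leak, LeakSpec):
        schedule: list[tuple[float, LeakSpec]] = [(0.0, leak)]
    else:
        schedule = sorted(leak, key=lambda s: s[0])
        if not schedule or schedule[0][0] > 0.0:
            schedule = [(0.0, LeakSpec.no_leak())] + list(schedule)

    mode = ws.SyncMode(sync_mode)
    cfg = detector_cfg or ws.DetectorConfig()
    onset_det = ws.OnsetDetector(cfg)
    cycle_det = ws.CyclingDetector(cfg)

    state = psc.ControllerState(paw_command=settings.peep)
    rng = np.random.default_rng(seed)

    dt = 1.0 / internal_rate
    n_sub = internal_rate // DECISION_RATE
    dt_dec = 1.0 / DECISION_RATE
    total = record_from + duration
    n_frames = int(round(total * DECISION_RATE))
    n_rec_frames = int(round(duration * DECISION_RATE))
    skip_frames = n_frames - n_rec_frames
    n_samples = n_rec_frames * n_sub

    chan = {name: np.empty(n_samples) for name in WaveformRecord.CHANNEL_NAMES}
    events: list[Event] = []

    r, c = mechanics.resistance, mechanics.compliance
    rc = CIRCUIT_RESISTANCE
    denom = r + rc + dt / c
    k_ins = 1.0 - math.exp(-dt * math.log(10.0) / settings.pressurization_slope)
    # symmetric first-order release toward PEEP on exhalation
    k_exh = k_ins
    peep, ps = settings.peep, settings.ps_level

    volume = c * peep
    p_vent = peep
    paw = peep
    insufflation = False
    spec = schedule[0][1]
    next_step = 1
    effort_was_active = False
    pmus_fn = lambda t: generate_pmus(effort, t)  # noqa: E731
    hold = effort.hold_time
    period = effort.period

    use_sync_trig = mode.inspiratory_active
    use_sync_cyc = mode.expiratory_active

    i_out = 0
    for frame in range(n_frames):
        t_frame = frame * dt_dec
        recording = frame >= skip_frames
        rel_t = t_frame - record_from
        # leak-schedule step times are relative to the recording start; a
        # leak_change event is logged only when the leak actually changes
        while next_step < len(schedule) and rel_t >= schedule[next_step][0] - 1e-9:
            new_spec = schedule[next_step][1]
            changed = (
                new_spec.level != spec.level or new_spec.kind != spec.kind
            )
            spec = new_spec
            if recording and changed:
                events.append(
                    Event(
                        round(rel_t, 6),
                        "leak_change",
                        {"level": spec.level, "kind": spec.kind},
                    )
                )
            next_step += 1

        for sub in range(n_sub):
            t = t_frame + sub * dt
            phase_t = math.fmod(t, period)
            pmus = _pmus_scalar(effort, phase_t)
            # effort event logging at internal resolution
            active = phase_t < hold
            if active and not effort_was_active and recording:
                events.append(Event(round(t - record_from, 6), "effort_onset", {}))
            if (not active) and effort_was_active and recording:
                events.append(Event(round(t - record_from, 6), "effort_end", {}))
            effort_was_active = active

            target = peep + ps if insufflation else peep
            p_vent += (target - p_vent) * (k_ins if insufflation else k_exh)
            q_leak_lpm = leak_flow(paw, spec, insufflation)
            q_leak_ls = q_leak_lpm / 60.0
            q_lung_ls = (p_vent - rc * q_leak_ls - pmus - volume / c) / denom
            volume += dt * q_lung_ls
            paw = p_vent - rc * (q_lung_ls + q_leak_ls)
            if not math.isfinite(volume):
                raise FloatingPointError(
                    f"simulation diverged at t={t:.3f}s "
                    f"({mechanics.label}, PS {ps}, {spec.level})"
                )
            if recording:
                chan["paw"][i_out] = paw
                q_lung_lpm = q_lung_ls * 60.0
                chan["q_lung"][i_out] = q_lung_lpm
                chan["q_leak"][i_out] = q_leak_lpm
                chan["q_circuit"][i_out] = q_lung_lpm + q_leak_lpm
                chan["pmus"][i_out] = pmus
                chan["volume"][i_out] = volume
                chan["vent_phase"][i_out] = 1.0 if insufflation else 0.0
                i_out += 1

        # ---- 50 Hz controller / detector decision on sensed signals ----
        q_circ_lpm = (q_lung_ls + q_leak_ls) * 60.0
        if noise is not None:
            paw_s = paw + rng.normal(0.0, noise.sigma_paw)
            q_s = q_circ_lpm + rng.normal(0.0, noise.sigma_flow)
        else:
            paw_s, q_s = paw, q_circ_lpm
        t_dec = t_frame + dt_dec  # decision applies at the end of the frame
        t_ev = round(t_dec - record_from, 6)
        state.acc_q += q_s
        state.acc_sqrtp += math.sqrt(max(paw_s, 0.0))

        if not insufflation:
            state.exhal_tail.append((q_s, paw_s))
            state.t_phase += dt_dec
            onset_fired = onset_det.update(q_s)
            if onset_fired and recording:
                events.append(Event(t_ev, "sync_onset", {}))
            if use_sync_trig:
                do_trigger = onset_fired
            else:
                do_trigger = psc.check_trigger(state, (paw_s, q_s), settings)
            if do_trigger:
                psc.update_leak_estimate(state, state.t_phase)
                state.phase = "insufflation"
                state.t_phase = 0.0
                state.peak_insp_flow = 0.0
                state.trigger_count = 0
                insufflation = True
                onset_det.reset()
                cycle_det.reset()
                if recording:
                    events.append(Event(t_ev, "trigger", {"mode": mode.value}))
        else:
            state.t_phase += dt_dec
            comp = q_s - state.leak_estimate_coeff * math.sqrt(max(paw_s, 0.0))
            state.peak_insp_flow = max(state.peak_insp_flow, comp)
            cyc_fired = cycle_det.update(q_s)
            if cyc_fired and recording:
                events.append(Event(t_ev, "sync_cycle", {}))
            if use_sync_cyc:
                do_cycle = (
                    cyc_fired and state.t_phase >= cfg.min_insufflation
                ) or state.t_phase >= settings.max_insufflation - 1e-9
            else:
                do_cycle = psc.check_cycle_off(state, (paw_s, q_s), settings)
            if do_cycle:
                state.phase = "exhalation"
                state.t_phase = 0.0
                state.cycle_count = 0
                state.exhal_tail.clear()
                insufflation = False
                onset_det.reset()
                cycle_det.reset()
                if recording:
                    events.append(Event(t_ev, "cycle_off", {}))

    events.sort(key=lambda e: (e.t, e.type))
    return WaveformRecord(float(internal_rate), chan, events)


def _pmus_scalar(profile: EffortProfile, phase: float) -> float:
    """Scalar fast path of generate_pmus for the inner loop."""
    a = profile.amplitude
    if a == 0.0:
        return 0.0
    if phase < profile.rise_time:
        return -a * phase / profile.rise_time
    if phase < profile.hold_time:
        return -a
    return -a * math.exp(-(phase - profile.hold_time) / profile.relax_tau)


# --------------------------------------------------------------------------
# Leak calibration
# --------------------------------------------------------------------------

def breath_averaged_leak(record: WaveformRecord, period: float, discard: float = 10.0) -> float:
    """Mean leak flow (L/min) over the largest whole number of effort periods
    after discarding an initial transient."""
    fs = record.sample_rate
    i0 = int(round(discard * fs))
    n_per = int(round(period * fs))
    n_whole = (len(record) - i0) // n_per
    if n_whole < 1:
        raise ValueError("record too short for breath averaging")
    sl = record.channels["q_leak"][i0 : i0 + n_whole * n_per]
    return float(sl.mean())


def calibrate_leak(
    level: str,
    mechanics: RespiratoryMechanics | None = None,
    vent_settings=None,
    *,
    kind: str = "inspiro-expiratory",
    effort: EffortProfile | None = None,
    sim_duration: float = 70.0,
    discard: float = 10.0,
    tol_frac: float = 0.01,
    max_iter: int = 50,
) -> LeakSpec:
    """Find the orifice coefficient delivering the target breath-averaged leak.

    The reference condition is steady closed-loop NIV-PS with normal
    mechanics, PS 8, PEEP 5 and synchronization off; the coefficient is
    bisected until the breath-averaged leak over >= 60 s matches the level's
    target within ``tol_frac``.  Deterministic (noise off).
    """
    from . import ps_controller as psc

    if level == "L0":
        raise ValueError("L0 needs no calibration")
    target = LeakSpec._LEVELS[level]
    mechanics = mechanics or MECHANICS_PRESETS["normal"]
    vent_settings = vent_settings or psc.settings_for(mechanics.label, ps_level=8.0)
    effort = effort or effort_profile_for(mechanics.label, calibrate_effort())

    def averaged(coeff: float) -> float:
        spec = LeakSpec(kind, level, target, coeff)
        rec = simulate_condition(
            mechanics, effort, vent_settings, spec, "IS0", duration=sim_duration
        )
        return breath_averaged_leak(rec, effort.period, discard=discard)

    lo, hi = 0.0, 30.0
    f_hi = averaged(hi)
    if f_hi < target:  # pragma: no cover - defensive bracket widening
        raise RuntimeError("calibration bracket too small")
    coeff = hi
    for _ in range(max_iter):
        coeff = 0.5 * (lo + hi)
        f = averaged(coeff)
        if abs(f - target) <= tol_frac * target:
            return LeakSpec(kind, level, target, coeff)
        if f < target:
            lo = coeff
        else:
            hi = coeff
    raise RuntimeError(
        f"leak calibration did not converge after {max_iter} iterations"
    )


# --------------------------------------------------------------------------
# Full protocol
# --------------------------------------------------------------------------

def run_protocol(
    mechanics: RespiratoryMechanics,
    effort: EffortProfile,
    vent_settings,
    sync_mode: str,
    leak_kind: str,
    leak_specs: dict[str, LeakSpec],
    protocol: ProtocolSpec = ProtocolSpec(),
    seed: int | None = None,
    noise: NoiseSpec | None = None,
    detector_cfg=None,
) -> WaveformRecord:
    """Simulate the full leak-change protocol of one condition.

    ``leak_specs`` maps levels to calibrated LeakSpecs of the requested kind
    (L0 is filled in automatically).  Event log contains every leak change
    and all controller/detector events; reproducible given ``seed``.
    """
    specs = dict(leak_specs)
    specs.setdefault("L0", LeakSpec.no_leak(leak_kind))
    for lv, sp in specs.items():
        if sp.kind != leak_kind:
            raise ValueError(f"leak spec for {lv} has kind {sp.kind!r}, expected {leak_kind!r}")
    schedule, duration = _leak_schedule_from_protocol(protocol, specs, effort.period)
    return simulate_condition(
        mechanics,
        effort,
        vent_settings,
        schedule,
        sync_mode,
        duration=duration,
        detector_cfg=detector_cfg,
        noise=noise,
        seed=seed,
        record_from=protocol.stabilization_before_recording,
    )
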