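"""Waveform-shape synchronization: effort-onset and end-of-inspiration detectors.

The published principle behind automated waveform synchronization is that a
short period of passive inflation follows the end of active inspiration; on
the flow-time curve this is a transition from a fast to a slow exponential
decay of inspiratory flow.  This module operationalizes that principle:

* cycling-off: the decay rate ``lambda`` of inspiratory flow, estimated by
  least squares on ``-ln(flow)`` over a short window, drops by more than a
  set ratio between two adjacent windows;
* triggering: during exhalation the passive expiratory flow trajectory
  (an exponential toward the leak-offset asymptote) is extrapolated one
  sample ahead; an inspiratory effort makes the observed flow exceed the
  prediction by a persistent margin.  Because the leak offset is absorbed
  into the fitted asymptote, a constant leak does not fire the detector.

The commercial implementation is proprietary; every numeric parameter here
is a documented choice of this package, exposed in :class:`DetectorConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "SyncMode",
    "DetectorConfig",
    "flow_decay_rate",
    "CyclingDetector",
    "OnsetDetector",
    "detect_end_of_active_inspiration",
    "detect_inspiratory_effort",
    "apply_sync_mode",
]

SAMPLE_RATE = 50.0  # Hz; the detectors run at the recording resolution


class SyncMode(str, Enum):
    """Activation mode of the synchronization algorithm.

    IS0 leaves both comparator decisions to the controller; ISI replaces
    only triggering, ISE only cycling-off, ISIE both.  The 2 s maximum
    insufflation cap is enforced by the controller in every mode.
    """

    IS0 = "IS0"
    ISI = "ISI"
    ISE = "ISE"
    ISIE = "ISIE"

    @property
    def inspiratory_active(self) -> bool:
        return self in (SyncMode.ISI, SyncMode.ISIE)

    @property
    def expiratory_active(self) -> bool:
        return self in (SyncMode.ISE, SyncMode.ISIE)


@dataclass(frozen=True)
class DetectorConfig:
    """Tunable parameters of both detectors (all positive).

    window: length (s) of each decay-rate estimation window.
    decay_ratio_threshold: fires when lambda_current <= threshold * lambda_prev.
    min_insufflation: earliest cycling-off time (s) after the trigger.
    onset_deviation_threshold: flow excess (L/min) over the passive
        extrapolation that counts as an effort.
    onset_persistence: time (s) the excess must persist.
    """

    window: float = 0.10
    decay_ratio_threshold: float = 0.5
    min_insufflation: float = 0.2
    onset_deviation_threshold: float = 2.0
    onset_persistence: float = 0.04

    def __post_init__(self) -> None:
        if min(
            self.window,
            self.decay_ratio_threshold,
            self.min_insufflation,
            self.onset_deviation_threshold,
            self.onset_persistence,
        ) <= 0:
            raise ValueError("all detector parameters must be positive")


def flow_decay_rate(flow_window, sample_rate: float = SAMPLE_RATE):
    """Exponential decay rate (1/s) of a flow window, or None if not evaluable.

    Least-squares slope of ``-ln(flow)`` against time.  Positive for
    decaying flow, zero for constant flow, negative for rising flow.  Any
    non-positive sample (or a window of fewer than 3 samples) makes the
    window not evaluable.
    """
    flow = np.asarray(flow_window, dtype=float)
    if flow.size < 3 or np.any(flow <= 0.0):
        return None
    t = np.arange(flow.size) / sample_rate
    slope = np.polyfit(t, -np.log(flow), 1)[0]
    return float(slope)


class CyclingDetector:
    """Stateful end-of-active-inspiration detector (fast->slow decay).

    Feed one sensed circuit-flow sample per 50 Hz frame of the insufflation
    via :meth:`update`; it returns True on the frame where the decay-rate
    ratio between the two most recent adjacent windows first falls at or
    below the configured threshold.  Causal: uses only samples at or before
    the event time.
    """

    def __init__(self, cfg: DetectorConfig, sample_rate: float = SAMPLE_RATE):
        self.cfg = cfg
        self.fs = sample_rate
        self.w = max(3, int(round(cfg.window * sample_rate)))
        self.reset()

    def reset(self) -> None:
        self._hist: list[float] = []
        self._peak = -np.inf
        self._fired = False

    def update(self, flow: float) -> bool:
        if self._fired:
            return False
        self._hist.append(flow)
        self._peak = max(self._peak, flow)
        n = len(self._hist)
        t_phase = n / self.fs
        if t_phase < self.cfg.min_insufflation or n < 2 * self.w:
            return False
        if flow >= self._peak:  # not past peak flow yet
            return False
        prev = self._hist[-2 * self.w : -self.w]
        cur = self._hist[-self.w :]
        lam_prev = flow_decay_rate(prev, self.fs)
        lam_cur = flow_decay_rate(cur, self.fs)
        if lam_prev is None or lam_cur is None:
            return False
        if lam_prev <= 0.0 or lam_cur < 0.0:  # rising/flat: not evaluable for cycling
            return False
        if lam_cur <= self.cfg.decay_ratio_threshold * lam_prev:
            self._fired = True
            return True
        return False


class OnsetDetector:
    """Stateful inspiratory-effort onset detector for the exhalation phase.

    Maintains a 0.3 s buffer of passive expiratory flow; at each frame the
    buffer is extrapolated one step ahead assuming an exponential approach
    to an (unknown) asymptote, estimated from first differences.  Persistent
    positive deviation of the observed flow beyond the threshold fires the
    detector.  Samples that already deviate are not admitted to the buffer,
    so the passive model is not polluted by the effort itself.
    """

    HISTORY = 15  # samples = 0.3 s at 50 Hz
    _FLAT_TOL = 0.05  # L/min; below this the trajectory is treated as flat

    def __init__(self, cfg: DetectorConfig, sample_rate: float = SAMPLE_RATE):
        self.cfg = cfg
        self.fs = sample_rate
        self._persist = max(1, int(round(cfg.onset_persistence * sample_rate)))
        self.reset()

    def reset(self) -> None:
        self._buf: list[float] = []
        self._count = 0
        self._fired = False

    def _predict(self) -> float:
        """One-step-ahead passive prediction.

        Upper envelope of (i) a geometric-increment exponential fit toward
        the (leak-offset) asymptote and (ii) a linear continuation of the
        recent slope.  Expiratory flow recovers toward its asymptote with a
        decaying slope, so both predictors bound the next passive sample
        from above and passive expiration cannot fire the detector, even
        when early expiration mixes several decay rates.
        """
        y = np.asarray(self._buf)
        d = np.diff(y)
        if np.max(np.abs(d)) < self._FLAT_TOL:
            return float(y[-1])
        linear = float(y[-1] + max(0.0, np.mean(d[-3:])))
        # geometric ratio of successive increments (lag-1 least squares)
        num = float(np.dot(d[1:], d[:-1]))
        den = float(np.dot(d[:-1], d[:-1]))
        if den <= 0.0:
            return linear
        rho = num / den
        if not (0.0 < rho < 0.999):
            # nearly linear trend, or non-monotone/unstable fit
            return linear if rho >= 0.999 else max(linear, float(np.mean(y[-3:])))
        n = y.size
        x = rho ** np.arange(n)
        a_mat = np.array([[n, x.sum()], [x.sum(), np.dot(x, x)]])
        b_vec = np.array([y.sum(), np.dot(x, y)])
        try:
            a, b = np.linalg.solve(a_mat, b_vec)
        except np.linalg.LinAlgError:  # pragma: no cover - singular fit
            return linear
        return max(linear, float(a + b * rho**n))

    def update(self, flow: float) -> bool:
        if self._fired:
            return False
        if len(self._buf) < self.HISTORY:
            self._buf.append(flow)
            return False
        pred = self._predict()
        dev = flow - pred
        if dev >= self.cfg.onset_deviation_threshold:
            self._count += 1
        else:
            self._count = 0
            self._buf.append(flow)
            del self._buf[0]
        if self._count >= self._persist:
            self._fired = True
            return True
        return False


def detect_end_of_active_inspiration(stream, cfg: DetectorConfig | None = None):
    """Event time (s from insufflation start) of the fast->slow decay
    transition in an insufflation flow stream, or None.

    ``stream`` is the sequence of 50 Hz circuit-flow samples from the start
    of insufflation.  Convenience wrapper over :class:`CyclingDetector`.
    """
    det = CyclingDetector(cfg or DetectorConfig())
    for i, flow in enumerate(stream):
        if det.update(flow):
            return (i + 1) / det.fs
    return None


def detect_inspiratory_effort(stream, cfg: DetectorConfig | None = None):
    """Event time (s from exhalation start) of an inspiratory-effort onset
    in an exhalation flow stream, or None.  Wrapper over :class:`OnsetDetector`."""
    det = OnsetDetector(cfg or DetectorConfig())
    for i, flow in enumerate(stream):
        if det.update(flow):
            return (i + 1) / det.fs
    return None


def apply_sync_mode(mode: "SyncMode | str", controller) -> None:
    """Wire the synchronization mode into a controller-like object.

    Sets ``use_sync_trigger``/``use_sync_cycling`` flags per mode; in
    inactive phases the detectors still run (their events are logged for
    analysis) but the comparator decisions stand.
    """
    mode = SyncMode(mode)
    controller.use_sync_trigger = mode.inspiratory_active
    controller.use_sync_cycling = mode.expiratory_active
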