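# Methods

## The virtual bench

`nivbench` replaces a physical NIV bench — a two-compartment test lung
driven by one ventilator to simulate breathing effort, assisted by a second
ventilator in NIV pressure support — with a closed-loop simulation built
from four coupled pieces: a lung, an effort source, a leak, and a
controller.

### Lung and circuit

The lung is a single compartment with the equation of motion
`q_lung = (Paw − Pmus − V/C)/R`. Volume is tracked above the relaxation
volume and initialized at its PEEP equilibrium `C·PEEP`. The three
mechanics presets (normal 78.3 mL/cmH₂O / 7.0 cmH₂O/L/s; obstructive
81.4 / 24.6; restrictive 49.4 / 7.0) give passive time constants of ~0.55,
~2.0 and ~0.35 s. Integration is semi-implicit (implicit in the elastic
term) at 500 Hz; controller decisions and recordings run at 50 Hz, the
acquisition rate of bench data loggers (20 ms resolution).

The ventilator is modelled as a first-order pressure source: the commanded
pressure approaches the phase target (PEEP, or PEEP + PS) exponentially,
reaching 90% of the step after the pressurization-slope setting (150 ms
normal, 100 ms obstructive/restrictive). Between the source and the airway
node sits a fixed circuit resistance of 2 cmH₂O/(L/s). This resistance is
what makes the bench *measurable*: a patient effort drawing flow through
the circuit pulls the airway pressure below PEEP before the ventilator
responds, producing the pressure nadir that defines trigger delay and the
sub-baseline area of the pressure–time product. Flow conservation
`q_circuit = q_lung + q_leak` holds exactly at the airway node where the
leak is attached; the recorded flow sensor sits between ventilator and
leak, as on the physical bench.

The physical bench's two-compartment coupling (driver compartment lifting
the second compartment by a rigid strip) is replaced by a direct
muscle-pressure source. The effort the second ventilator sees is fully
characterized by its occlusion indices, which the source reproduces, so
nothing is lost at the level of the signals the controller and analysis
observe.

### Effort source and occlusion calibration

Pmus(t) is periodic: a linear ramp to −amplitude over the rise time, a hold
until the end of the driver high-pressure phase (0.9 / 0.9 / 0.8 s per
mechanics — the "neural inspiratory time"), then an exponential release
with a 100 ms time constant. Periods of 3.3 / 4.3 / 3.2 s give breathing
rates of ~18 / 14 / ~19 cycles/min. A single amplitude is used for all
three mechanics.

Under an airway occlusion the lung volume cannot change, so the airway
deflection equals Pmus. Calibration is therefore closed-form: the amplitude
equals |Poccl| = 13.48 cmH₂O, and the ramp is sized to pass through P0.1 =
−5.58 cmH₂O at 100 ms, giving a rise time of ~0.24 s (close to the driver's
200 ms pressurization slope). `occlusion_test` verifies the round trip by
simulating ≥10 occluded efforts; targets with |P0.1| ≥ |Poccl|, or implying
a ramp longer than the hold, are rejected as infeasible.

### Leaks

Leaks follow a turbulent-orifice law `q = k·sign(Paw)·√|Paw|` in
(L/min)/√cmH₂O, either open throughout the breath (inspiro-expiratory) or
only during insufflation (inspiration-only). Because the bench targets are
stated as flows (9 and 20 L/min) without a reference pressure, `k` is
calibrated by bisection against the breath-averaged leak over ≥60 s of
steady closed-loop ventilation in a fixed reference condition: normal
mechanics, PS 8, PEEP 5, synchronization off. The calibration is
deterministic and converges to well under 1%; inspiration-only orifices
come out larger since they flow only part of the breath.

## The pressure-support controller

Triggering compares leak-compensated flow (`q_circuit − k̂·√Paw`) against
the 1.5 L/min threshold; cycling compares it against a per-mechanics
percentage of its inspiratory peak (25 / 40 / 15%). Both comparators
require two consecutive 50 Hz samples (debounce), and cycling is armed only
after a 100 ms refractory period with a real peak established. Insufflation
is hard-capped at 2 s, the NIV-mode default.

The leak estimate k̂ is updated once per breath at the trigger instant.
When the preceding exhalation contains a quiescent tail — the oldest half
of the last 200 ms is flat within 1 L/min — k̂ blends (weight 0.3/breath)
toward the median of `q_circuit/√Paw` over that tail, where patient flow is
near zero and the ratio isolates the orifice coefficient. When the tail is
not quiescent, which happens exactly when a large uncompensated leak
re-triggers the ventilator while the lung is still emptying, that tail
never shows the bare leak and a median-ratio update would stall at a
self-consistent underestimate; the update then falls back to a whole-breath
flow balance, `Σq_circuit / Σ√Paw` over the frames since the previous
trigger, which isolates the coefficient because lung volume is
near-periodic breath to breath. The combination reproduces the behaviour
seen on real NIV modes: a transient burst of auto-triggering immediately
after an abrupt leak increase (the estimate lags by design), followed by
re-stabilization within roughly a minute, while inspiration-only leaks —
whose exhalations are long and quiet — correctly converge to k̂ ≈ 0 and
keep the trigger sensitive.

Sensor noise (optional, off by default: σ = 0.2 L/min on flow, 0.1 cmH₂O on
pressure, seeded) perturbs only what the controller and detectors sense;
recorded channels stay exact so record-level invariants are testable.

## Waveform synchronization

The commercial algorithm's internals are proprietary; the module implements
only the published principle and every numeric parameter is an explicit,
configurable choice (`DetectorConfig`).

**Cycling-off** (end of active inspiration): the decay rate λ of
inspiratory flow is the least-squares slope of −ln(flow) over a 100 ms
window; the detector fires when λ of the current window falls to ≤ 0.5× the
λ of the adjacent previous window — the fast-to-slow transition that marks
the onset of passive inflation. Windows containing non-positive samples or
rising flow are not evaluable; nothing fires before 200 ms of insufflation,
and the controller's 2 s cap always remains. With the bench's hold-type
effort this transition appears at the end of the effort *release* provided
circuit flow stays positive there — which is precisely the situation in the
conditions where cycling synchrony matters (slow lungs and/or inspiratory
leak offsets); when flow goes negative instead (fast lung, no leak), the
detector abstains and the comparator/cap governs.

**Triggering** (effort onset): during exhalation the passive expiratory
flow trajectory — an exponential recovery toward the leak-offset asymptote
— is extrapolated one sample ahead from the last 300 ms. The predictor is
the upper envelope of a geometric-increment exponential fit and a linear
slope continuation; since passive recovery has a decaying slope, both bound
the next passive sample from above and passive expiration cannot fire the
detector even when early expiration mixes several decay rates. An effort
makes observed flow exceed the prediction by ≥ 2 L/min for ≥ 40 ms.
Deviating samples are withheld from the model buffer, so the passive fit is
not polluted by the effort itself. A constant leak is absorbed into the
asymptote — the mechanism by which waveform triggering resists the
leak-induced auto-triggering that threshold triggering suffers.

Activation modes mirror clinical practice: IS0 (both comparators), ISI
(detector triggers, comparator cycles), ISE (the reverse), ISIE (both
detectors). Detectors always run and log their events even when inactive.

## Measurement pipeline

Records are decimated to 50 Hz by sample picking (no anti-alias filter —
the loggers being emulated sample instantaneous sensor values), and event
times snap to the 20 ms grid; all derived timings are therefore multiples
of 20 ms. Per effort: trigger delay Td = effort onset → airway-pressure
nadir (searched within 0.5 s; defined only for triggered cycles);
inspiratory time in excess Tiex = end of neural inspiration → return of
circuit flow to the end-expiratory baseline + 1 L/min (the tolerance is
needed at 50 Hz; the baseline is the mean flow over the last 100 ms of the
preceding expiration and thus includes any steady leak offset). The
pressure–time products use the end-expiratory pressure P_ee (mean over the
same 100 ms window): area A integrates the sub-baseline deviation from
effort onset to the first upward re-crossing; areas B and C integrate the
positive deviation to 300 ms and 300–500 ms after onset; PTP_trig = A ≤ 0,
PTP300 = B − |A|, PTP500 = B + C − |A|. Integration is trapezoidal on the
50 Hz grid. If pressure never re-crosses baseline within 500 ms the cycle
is flagged and B = C = 0.

Steady-state selection scans the 14 cycles before each leak change, newest
first, for 5 consecutive triggered cycles; failure marks the condition
unstable and no timing metrics are reported. Classical asynchronies are
counted over windows of exactly 10 driver cycles before (steady-state) and
after (post-modification) each leak change: auto-triggering (ventilator
cycle with no concurrent driver inspiratory phase, ±20 ms), ineffective
effort (no ventilator trigger during the effort), double-triggering
(expiratory gap < 50% of the mean *ventilator* insufflation time, second
cycle not effort-driven), late/early cycling (insufflation > 2× / < ½× the
mean neural inspiratory time, i.e. the driver hold time). A cycle carries
at most one of {late, early} plus at most one of {auto, double};
ineffective attaches to efforts. AI divides event counts by triggered
cycles plus ineffective efforts.

Condition comparisons use the two-sided Wilcoxon rank-sum test, exact by
full enumeration of group assignments (with midranks, so ties are handled
and identical samples give p = 1) for groups of ≤ 10 values — the natural
regime for 5-cycle steady-state samples — and the tie-corrected normal
approximation above that.

## Protocol and problem sizes

The full protocol per condition is 15 baseline no-leak cycles followed by
the leak sequence L0→L9→L20→L9→L0→L20→L0, one step every 120 s, after a
300 s unrecorded stabilization — these are the `ProtocolSpec` defaults. The
test suite and the acceptance script run the same machinery at desk scale
(steps of tens of seconds, stabilizations of seconds to tens of seconds,
10-seed replicates for the stochastic directional checks), which keeps the
whole suite under a minute while exercising every code path; the directional
margins observed (e.g. Tiex medians of ~1.3 s vs ~0.2 s) are far wider than
the run-length sensitivity.

## What the generator does and does not emulate

Emulated: the closed-loop interaction of effort, lung mechanics, leak and
controller; calibrated occlusion indices and leak flows; transient
auto-triggering after leak increases; cycling failure against inspiratory
leaks; 50 Hz acquisition quantization; optional sensor noise. Not emulated:
mask/interface dynamics and rebreathing, humidifier and circuit compliance,
the physical two-compartment lung coupling, vendor-specific controller
internals (the leak compensation and the synchronization detectors here are
this package's own documented designs that reproduce the published
behaviour, not the proprietary algorithms), and patient variability —
efforts are strictly periodic with fixed shape. Passing tests therefore
demonstrate the internal consistency of the measurement pipeline and the
directional effects of waveform synchronization in this model, not numeric
equivalence with any physical bench or commercial device.

## Numerical choices and degenerate inputs

Semi-implicit integration keeps the stiff obstructive/restrictive dynamics
stable at 2 ms steps; divergence (non-finite state) aborts with the
condition label. The 90%-of-step reading of the pressurization-slope
setting is a documented convention (vendor semantics are unpublished).
Untriggered cycles raise on Td/Tiex/PTP and are excluded from statistics.
Zero-denominator AI raises. Leak calibration brackets k in [0, 30]
(L/min)/√cmH₂O and reports non-convergence after 50 bisections. Detector
edge cases (non-positive flows, windows shorter than 3 samples, rising
flow) return "not evaluable" rather than firing.

## Known limitations

Dynamic hyperinflation: with the obstructive time constant (~2 s) and the
driver's expiratory time (~3 s), the single-compartment model retains a
volume offset at end-expiration (~2 cmH₂O intrinsic PEEP). The physical
bench avoided this by construction; here it lengthens obstructive trigger
delays slightly, which is physiologically plausible but not
bench-verified. Steady-state volume is cycle-periodic, which is what the
volume-stability property asserts. The restrictive presets can remain
unstable under sustained leaks (persistent asynchrony), as unstable
restrictive setups also occur on physical benches; such conditions are
reported with the stability flag rather than suppressed.
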