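# Methods

## Overview

`efsgait` models, end to end, a non-contact gait-measurement chain based on
electrostatic field sensing (EFS), alongside the foot-pressure (FSR insole)
chain conventionally used as reference. The package contains five layers:

1. **Kinematic truth** (`efsgait.kinematics`) — per-cycle gait timing and a
   foot trajectory (height `h(t)`, sole–ground equivalent area `s_s(t)`);
2. **Sensor forward models** (`efsgait.sensors`) — the induced-current EFS
   channel with its analog front end, and the FSR voltage channel;
3. **Event detection** (`efsgait.detection`) — initial contact (IC, heel
   strike) and separate event (SE, foot-off) on each channel;
4. **Temporal parameters** (`efsgait.parameters`) — per-cycle Tg, Ts, Tw,
   cadence, RS, RW;
5. **Agreement statistics** (`efsgait.agreement`) — event-error statistics,
   cycle accuracy, Pearson r with qualitative grading, ICC(2,1).

Everything downstream of layer 1 treats the schedule as hidden truth, so
detector performance can be measured exactly.

## Gait timing model

Cycle durations are drawn i.i.d. from a truncated normal distribution
(rejection sampling; the truncation bounds are hard clips). The three pace
profiles are, in ms: fast 990 ± 120 on [870, 1153], normal 1198 ± 110 on
[1088, 1398], slow 1498 ± 75 on [1358, 1697]. Per-cycle stance fractions are
truncated-normal around 0.60 (sd 0.02, clipped to [0.4, 0.8]), matching the
~60 % stance / 40 % swing split of healthy gait. A schedule of `n` cycles
has `n + 1` IC and `n` SE events, strictly alternating.

## Foot trajectory

The height profile of each swing is a **smoothed trapezoid**: cosine S-ramps
of duration `lift_s` (default 50 ms, capped at 30 % of the swing) at
foot-off and landing, and a flat plateau at `h_max` (default 0.15 m)
between them. This shape encodes the physical observation that the vertical
foot speed — and therefore the induced current, which is proportional to
`dh/dt` while the foot is airborne — is largest just after foot-off and
just before contact. A profile whose maximum slope sits mid-swing (e.g. a
single raised cosine across the whole swing) would displace the current
peaks by a quarter swing (~100–150 ms) from the events and make peak-based
detection systematically wrong; with the trapezoid the noiseless peak sits
`lift_s / 2` (25 ms) after SE and the trough 25 ms before IC. This residual
offset is the dominant, essentially constant bias of the EFS detector; it
cancels exactly in cycle-duration (Tg) differences.

The contact area `s_s(t)` is `s_max` (0.025 m², an adult sole) during flat
stance, ramps down to `s_min` (0.002 m², residual toe/heel proximity) over
the final `roll_fraction` (0.15) of stance and back up over the first
`roll_fraction` after contact, and stays at `s_min` through swing. Because
`h = 0` throughout stance, the area ramps do not themselves generate
current; they exist so the forward model's second term
(`-h/S_s² · dS_s/dt`) is exercised structurally and configurable. `s_min`
is strictly positive so the potential never divides by zero.

Traces carry a 0.5 s lead-in before the first IC and 0.5 s padding after
the last, as a real recording that brackets the analysed steps would.

## Electrostatic forward model

With body charge `Q_B`, air permittivity `ε_a`, and feet-to-ground
capacitance `C_f = 2 ε_s S_s / d_e` (sole permittivity `ε_s`, thickness
`d_e`), the body potential is

    U_B(t) = Q_B (1/C_f + h(t) / (ε_a s_s(t)))

and the electrode current is `I = C · dU_B/dt` through the body–electrode
coupling capacitance `C` (central differences on the simulation grid). The
electrode's own potential is neglected: it sits at virtual ground behind
the sampling resistor, so its feedback on the charge balance is negligible.

Defaults: `Q_B = 1e-8 C`, `ε_s = 2.5 ε_0`, `d_e = 1 cm` (giving
`C_f ≈ 0.11 nF`), `C = 1e-16 F`. The coupling capacitance of an electrode
a few metres from the body is a small fraction of a femtofarad; with these
defaults the swing bursts peak near ±270 pA, i.e. volts after I–V
conversion. Absolute amplitude is uncalibrated — no measured values exist
for `Q_B`, `C` or the noise floor — so only the timing structure of the
waveform is validated; all constants are configurable.

### Front end

The current is converted at 10 mV/pA across a 10 GΩ sampling resistor,
low-pass filtered at 20 Hz (foot motion lives at 1–2 Hz; the filter
suppresses mains and other high-frequency fields) and sampled at 1 kHz.
Numerical choices:

* the filter is an order-4 Butterworth applied forward–backward
  (`sosfiltfilt`), i.e. zero phase, so filtering never shifts event times;
* simulation runs on a 4 kHz internal grid and decimates by slicing after
  the low-pass (nothing above 20 Hz survives, so no anti-alias stage is
  needed);
* no ADC quantisation is modelled; traces stay floating point.

Noise defaults: white input-referred current noise of 20 pA sd and a 50 Hz
mains component of 50 pA amplitude, both added before filtering. The 20 Hz
zero-phase filter attenuates the mains term by >60 dB and shrinks the white
noise by roughly √(bandwidth ratio), leaving ~mV-scale residuals against
~2.7 V signal peaks. These defaults are deliberately benign: the goal is a
realistic but clean laboratory recording, and they are part of the recorded
simulation conditions.

## Pressure channel

Each stance is a trapezoid: linear rise from the baseline over `ramp_s`
(default 80 ms) starting at IC, linear fall ending at SE. The baseline is a
slow sinusoid in `[0, drift_amp]` (default 0.1 V, period 20 s) modelling
no-load drift; the plateau is `v_full − drift_amp` above baseline so the
output respects the 0–2.5 V range; Gaussian noise (20 mV sd) is added and
the result clipped to [0, 2.5] V. The rise and fall must not overlap, so
`ramp_s` must be shorter than half the shortest stance.

## Detectors

**Pressure (three steps).** (1) Stance zones from threshold crossings of
the smoothed trace at 1 V (well above no-load drift, well below the loaded
plateau); a boundary partial stance (e.g. a trace that starts mid-plateau
after trimming) is dropped, while two same-direction interior edges raise a
malformed-signal error with the sample index. (2) Because the no-load level
drifts, the anchor for each event is the local minimum bounding the edge,
found by walking from the smoothed derivative's peak on the edge to its
zero crossing (pre-rise minimum for IC, post-fall minimum for SE).
(3) Offset correction: with `offset = 3 %` of the cycle's local max − min
swing, IC is the first time after the pre-rise minimum at which the **raw**
signal exceeds `min + offset`, SE the last such time before the post-fall
minimum. Using the raw samples in step 3 keeps the noiseless detector exact
to one sample against the linear-ramp crossing algebra; the smoothed trace
is used only for edges and derivatives. The crossing must be sustained for
`crossing_sustain` (default 5 ms): an isolated noise excursion above the
offset level in the no-load window next to the anchor minimum would
otherwise fire the event tens of milliseconds off roughly once per few
hundred events, while on a clean monotone ramp the sustain requirement
changes nothing. On the default simulated channel
the offset crossing sits ~2.4 ms inside each ramp — a constant bias that
cancels in Tg.

**EFS (peak extraction).** The trace is smoothed with a centred moving
average (50 ms), then positive peaks (SE) and negative troughs (IC) are
extracted with a prominence floor of 20 % of the trace's peak-to-peak swing
and a minimum same-kind separation of 0.3 s. Alternation is enforced by
dropping the less prominent of any adjacent same-kind pair (ties keep the
earlier). The mapping peak→SE / trough→IC follows the sign of the physics
(current positive while the foot lifts); negating the trace swaps the
labels exactly, and an optional `auto_polarity` flag recovers the labels on
an inverted electrode by checking which inter-event gap pattern (stance
should be the longer, trough→peak gap) is consistent. The flag is off by
default because the simulator's polarity is known.

Both detectors report event times as `t0 + index/fs`, so they are exactly
translation-equivariant.

## Parameters and statistics

Per cycle: `Ts = SE − IC`, `Tw = IC_next − SE`, and `Tg := Ts + Tw`, which
makes the identity `Tg = Ts + Tw` hold exactly in floating point (defining
`Tw = Tg − Ts` instead can be off by one ulp). Cadence is `120000 / Tg[ms]`
steps/min (two steps per cycle). Partial cycles at the sequence boundaries
are dropped.

Event matching is greedy nearest-neighbour within a ±100 ms window, each
event used at most once. Cycle pairing between two detectors matches IC
events the same way and forms a Tg pair wherever two matched ICs are
consecutive on **both** sides, so a dropped event desynchronises at most
its neighbouring cycles. Accuracy is `100 − mean |%error|` over paired Tg.

Pearson r (with the two-sided t-transform p, via `scipy.stats.pearsonr`) is
graded excellent/good/fair/poor at 0.90/0.80/0.70. ICC(2,1) — two-way
random effects, absolute agreement, single measures (Shrout–Fleiss) — is
implemented from its ANOVA mean squares,

    ICC(2,1) = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE)),

with significance from `F = MSR/MSE` on `(n−1, (n−1)(k−1))` degrees of
freedom, and graded at 0.90/0.75/0.50. The test suite cross-checks the
implementation against an explicit-sums oracle and against
`pingouin.intraclass_corr`. In the single-session pipeline report the ICC
treats paired cycles as subjects and the two methods as raters.

The error histogram uses 5 ms bins over ±50 ms by default; values outside
the range are absorbed into the outermost bins so counts always total the
matched events.

## Pipeline

`run_pipeline` simulates both channels from one schedule, trims 2 s from
each end of the recording (walkers need an adjustment period before a
steady rhythm; only events inside the trimmed span are kept, none are
altered), runs both detectors, writes signals, events, per-cycle parameter
tables, and a validation report (JSON + flat key=value text), and logs the
seed and a config hash. All randomness derives from one seed through
`numpy.random.SeedSequence`, so runs are byte-reproducible.

## Problem sizes and what the tests show

The validation suites use 100 normal-pace cycles (~2 min of walking) for
event-timing and accuracy checks and 100 cycles per pace for the pooled
concurrent-validity check, sizes chosen to mirror a realistic lab session
(300 valid cycles) while keeping a full run in seconds. Under the default
conditions the EFS detector's event errors are a nearly constant ±25 ms
(half the lift ramp) with millisecond-scale jitter, Tg accuracy is ≈99.9 %,
and EFS-vs-pressure Tg correlation is r > 0.999.

Passing these checks shows that the detection algorithms recover the timing
structure the forward model encodes, at noise levels typical of a
controlled indoor recording. It does **not** show robustness to what the
simulator omits: double support and left/right interference on a single
electrode, amplitude variation with body–electrode distance and angle,
humidity/temperature effects on body charge, electrode drift,
non-stationary pathological gait, or FSR nonlinearity and hysteresis. The
constant 25 ms peak offset is a property of the simulated lift profile;
on real feet the offset depends on the actual foot-off kinematics and
would need calibration against a reference system.

## Known limitations

* Single-subject, single-foot analysis; the opposite foot can be
  superposed on the EFS channel (`both_feet=True`) but the detectors do not
  disambiguate feet — detection quality degrades by design in that mode.
* Absolute EFS amplitudes are arbitrary (uncalibrated `Q_B`, coupling, and
  noise); only prominence-relative thresholds are used downstream.
* The truncated-normal timing model draws cycles i.i.d.; real gait has
  serial correlation and drift.
* Detection is offline (whole-trace); no streaming mode.
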