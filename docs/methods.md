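# Methods

## The control problem

An anesthetized subject under a forced-air blanket must be held at a target
core temperature (38.0 °C for the normothermic porcine setting this package
emulates; pigs run slightly warmer than humans). The only actuator is a
commercial warming unit with a quantized setting space — four heat levels
(ambient ≈ 21 °C, 32, 38, 43 °C, each regulated within ±1.5 °C) crossed
with two usable blower speeds (slow ≈ 20 L/s, fast ≈ 23 L/s; standby
deflates the blanket and is excluded from control). The sensor is a 1 Hz
arterial blood-temperature feed that suffers transient artifacts: cold-fluid
calibration injections and line flushes depress the reading by a degree or
two for tens of seconds.

## Controller

Every `eval_interval` seconds (default 120) the controller takes the
arithmetic mean of the valid samples in the elapsed window, forms the error
`e = target − mean`, updates the saturating action state
`s ← clamp(s + scaling_factor · e, −1, 1)` (integral mode, `s₀ = 0`;
gain default 0.7) and quantizes `s` onto the settings:

| s | setting |
|---|---------|
| s = −1 | ambient 21, fast |
| −1 < s ≤ −0.5 | ambient 21, slow |
| −0.5 < s ≤ 0 | 32 °C, slow |
| 0 < s ≤ 0.5 | 38 °C, slow |
| 0.5 < s < 1 | 43 °C, slow |
| s = 1 | 43 °C, fast |

Design points, with rationale:

* **Error sign.** The map sends `s = +1` to maximal heating, so negative
  feedback requires `e = target − mean` (a positive error means the subject
  is too cold). The convention is fixed here once and documented; the
  opposite sign would heat an already-hot subject.
* **Integral vs proportional.** The default accumulates the error, which is
  what makes the loop *anneal*: extreme settings are reached through several
  small steps and released just as gradually, avoiding lock-in at an extreme.
  The proportional mode (`s = clamp(c_s · e)`) is kept selectable because it
  is the natural one-line alternative and useful for comparison.
* **Interval semantics.** The six intervals are upper-inclusive exactly as
  tabulated, so `s = 0` commands (32 °C, slow) and the fast blower engages
  only at the exact saturation points ±1 — speed changes are reserved for
  extreme conditions, matching the observation that the slow/fast airflow
  difference (20 vs 23 L/s) is minor compared to the heat-level difference.
* **Windowing.** The mean uses all valid samples with timestamps in
  `(t − c_t, t]`; the window is cleared after each evaluation ("collect,
  average, repeat"). Evaluation fires on the wall clock (≥ `c_t` seconds
  since the last evaluation), not on a sample count, so gaps are tolerated:
  a lone sample after a long gap is evaluated as a partial window. An
  all-invalid window leaves the state untouched and holds the previous
  setting, but still advances the evaluation clock.
* **Artifact handling.** Nothing beyond the window mean: a 30 s, −2 °C
  artifact shifts a 120 s mean by −0.5 °C, i.e. one transient step of
  `Δs = 0.35`, corrected at the next evaluation. No explicit flush detector
  is part of the controller.

The incremental implementation is verified bit-for-bit against a brute-force
oracle (store every sample, recompute each mean in full, textbook clamp,
independent interval-table lookup) on random irregular streams.

## Device emulator and protocol

The warming unit plus its remote-control add-on board are emulated as a
state machine with a byte-level codec: ASCII payloads framed by STX (0x02) /
ETX (0x03); the unit's ten status indicators (fault, temperature-in-range,
three speeds, four heat levels, one reserved) reported once per second as a
10-character '0'/'1' string; settings changed by `S:X` commands that press
front-panel switch X ∈ 1..8. The physical pin order and switch wiring are
not published, so a canonical assignment is fixed and documented — indicator
order (fault, in-range, standby, slow, fast, ambient, 32, 38, 43, reserved),
switches 1–3 = speeds, 4–7 = heat levels, 8 unassigned — and both maps are
parameters for anyone wiring it differently. Baud rate (9600) and the 150 ms
press hold are retained as documentation constants only; no bit timing is
simulated. Setting transitions are planned as minimal press sequences
(heat first, then speed; length ≤ 2), verified by exhaustive enumeration of
all 144 transitions.

## Synthetic plant

There is no published thermal model of the original subjects; the plant is
this package's own minimal construction that reproduces the relevant
phenomenology. It is a single well-mixed compartment,

    C dT/dt = P_met(t) − k_ambient (T − T_amb) − k_blanket(speed) (T − T_air),

integrated by explicit Euler at dt = 1 s. Time constants are hours
(C/k ≈ 2–8 h), so the scheme is far from its stability limit; against the
exact exponential solution of the homogeneous case the 1 s trajectory stays
within ~1e-4 °C (tested at a 0.01 °C tolerance).

Defaults (chosen once, for a ~42 kg juvenile pig in a 21 °C room under a
full-body blanket):

| parameter | default | why |
|---|---|---|
| mass | 42 kg | mid-range of the emulated subjects (~40–45 kg) |
| specific heat | 3500 J/(kg·K) | standard soft-tissue average |
| k_ambient | 5 W/K | passive losses; gives an uncontrolled time constant ≈ 8 h |
| k_blanket slow/fast | 12 / 14 W/K | ≈ half the convective upper bound ρ·c_p·flow at 20/23 L/s |
| basal power | 87 W | ≈ 2 W/kg anesthetized; uncontrolled equilibrium ≈ 38.4 °C |
| fever | 0 → 15 W, ramp 4 h → 16 h | drug-induced hyperthermia of long narcosis; drives the uncontrolled subject past 39.5 °C within ~24 h |
| noise sd | 0.02 °C | thermistor-grade sensor |
| artifacts | −2.0 °C × 30 s every 4 h | cardiac-output calibration injections |
| initial temp | 37.5 °C | mild post-preparation hypothermia |

Two structural consequences are intentional. First, maximal cooling
(ambient, fast) has an equilibrium near 26 °C, so the loop can always pull a
febrile subject back below target. Second, no setting balances the plant at
exactly 38.0 °C (the 38 °C/slow equilibrium sits at ≈ 38.1 °C, the next
level down at ≈ 33.9 °C), so the controller must alternate between adjacent
settings — the quantized-actuator ramp-and-correct pattern the design
anticipates.

**What the generator does not emulate:** multi-compartment core/skin
gradients, vasodilation heat redistribution at induction (only a crude
initial-condition offset), drifting sensor bias, and inter-individual
variability beyond the documented mass/fever grid. Passing closed-loop tests
therefore demonstrate the algorithm's behavior on a first-order thermal
load, not clinical performance on real patients; the blanket coupling
magnitude in particular is an order-of-magnitude estimate, not a calibrated
value.

## Trial metrics and replay

A trial is a 1 Hz CSV (`time_s,temp_c,heat,speed`, `#` metadata headers).
Metrics follow the time-in-range convention: each present sample counts one
second (gaps contribute nothing), a sample is outside a band when
|T − target| strictly exceeds the tolerance, and percentages / hourly rates
are rounded half-up to two decimals. Adaptions are counted as recorded
state transitions between consecutive rows (the recordings store device
state, not issued commands). Banding is computed on raw readings; a centered
120 s sliding-median filter (edges use the partial window) is available via
a flag for sensitivity analysis and display, since it suppresses exactly the
short artifacts the mean-based controller also absorbs.

`replay_controller` feeds recorded temperatures through the control law and
reports second-by-second agreement between predicted and recorded settings.
The predicted stream starts at the neutral state's setting (s = 0 →
32 °C/slow), which is also where `generate_trial` parks the emulator, so a
package-generated closed-loop trial replays at 100 % agreement by
construction — the loop's self-consistency oracle. Replays with a different
gain diverge on any non-constant trace.

## Problem sizes and tolerances

The test suite runs closed-loop rollouts of 6 simulated hours per
configuration (2 h settling excluded) across the documented 3×3 robustness
grid, 24 h for uncontrolled-drift checks, and 100 random 10 000-sample
streams for the controller/oracle equivalence; the acceptance script runs
the full 90 h scenario at 1 Hz (324 000 steps). The Euler-vs-closed-form
tolerance is 0.01 °C; controller/oracle comparisons are exact (bit
identity); metric reproductions of the reference trial summaries are exact
at the published two-decimal precision.

## Known limitations

* The plant is linear and single-compartment; oscillation amplitudes and
  adaption rates depend on its invented coupling constants, so simulated
  change-per-hour counts need not match any particular recorded trial.
* The reference trials' raw 1 Hz recordings are not redistributed here;
  their metrics are validated through series reconstructed from the
  published summary counts, and full raw-sample replay is out of reach.
* The emulator's LED order and switch map are canonical choices, not the
  (unpublished) real wiring; both are configurable.
* The protocol has no checksums or error correction, faithfully to the
  emulated board; `ProtocolError` covers malformed frames only.
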