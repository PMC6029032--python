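# ttmloop

Closed-loop **targeted temperature management** (TTM) with a forced-air
warming blanket: a saturating annealing controller for a quantized actuator,
a software emulator of the warming unit and its serial remote-control
protocol, a lumped-parameter thermal model of an anesthetized subject, and a
replay/metrics engine for 1 Hz trial recordings.

Intended users are researchers in physiological closed-loop control and
critical-care device automation who want to study, reproduce or extend
automated forced-air TTM without bench hardware or animal data: the entire
loop — sensor, algorithm, actuator, subject — runs in software.

## The control law

The warming unit offers only discrete settings: heat levels
{ambient ≈ 21 °C, 32 °C, 38 °C, 43 °C} and blower speeds {slow ≈ 20 L/s,
fast ≈ 23 L/s} (standby deflates the blanket and is never commanded). Every
evaluation interval *c*<sub>t</sub> (default 120 s) the controller averages
the valid 1 Hz blood-temperature samples of the elapsed window — a filter
that absorbs flush and cold-injection artifacts of an arterial catheter —
and forms the feedback error

&nbsp;&nbsp;&nbsp;&nbsp;*e* = *T*<sub>tar</sub> − T̄

(positive ⇒ the subject is too cold). The error is accumulated into a
saturating action state

&nbsp;&nbsp;&nbsp;&nbsp;*s* ← clamp(*s* + *c*<sub>s</sub> · *e*, −1, 1),&nbsp;&nbsp;*s*₀ = 0,

with gain *c*<sub>s</sub> (default 0.7), and *s* is quantized onto the
device: *s* = −1 → (ambient, fast), (−1, −0.5] → (ambient, slow),
(−0.5, 0] → (32, slow), (0, 0.5] → (38, slow), (0.5, 1) → (43, slow),
*s* = 1 → (43, fast). Because no discrete setting balances the subject
exactly, the loop anneals to the two adjacent settings and alternates —
small temperature ramps corrected every couple of minutes. A purely
proportional mode (*s* = clamp(*c*<sub>s</sub>·*e*)) is selectable for
comparison.

Performance is measured as **time in range**: the fraction of trial seconds
with |T − T_tar| within ±0.5 °C and ±1.0 °C, plus the number of setting
adaptions per hour.

## Worked example

Simulate six hours of the closed loop on the default synthetic subject
(42 kg, febrile drift, noisy arterial sensor with periodic −2 °C
calibration-injection artifacts), then replay the recording:

```bash
$ ttmloop simulate --seed 1 --duration-h 6 --settling-h 2 --out sim.csv --report report.txt
trial           : simulated-closed-loop
target          : 38.0 degC
total duration  : 14400 s (first 7200 s settling excluded)
  +/-0.5 degC : outside 147 s, within 98.98%
  +/-1.0 degC : outside 30 s, within 99.79%
setting changes : 38 (9.50 per hour)

$ ttmloop replay sim.csv
evaluations        : 179
agreement          : 100.00% of seconds
changes recorded   : 55
changes predicted  : 55
```

After the two-hour settling phase the measured temperature stays within
±0.5 °C of the 38.0 °C target for 98.98 % of the time; the 30 s outside
±1.0 °C are exactly one scheduled −2 °C sensor artifact, not a real
excursion (the subject's true core temperature never leaves the band — the
acceptance script checks this on the full 90 h scenario). `replay` feeds the
recorded temperatures back through the control law and regenerates the
recorded settings at every second, confirming recording and controller are
consistent.

Other commands: `ttmloop generate` (open-loop/uncontrolled datasets),
`ttmloop evaluate` (metrics for any trial CSV, with `--column-map` for
foreign dialects and `--filtered` for 120 s sliding-median scoring), and
`ttmloop emulate` (drive the warming-unit emulator and print its framed 1 Hz
status messages). All outputs embed config, seed and version as `#` header
lines; identical seeds give byte-identical files.

The canonical trial CSV schema is `time_s,temp_c,heat,speed` with `heat` in
{21, 32, 38, 43} and `speed` in {standby, slow, fast}.

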