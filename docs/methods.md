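# Methods

## Model

The simulator implements a leaky integrate-and-fire neuron whose firing
nonlinearity is a hysteretic threshold-switching device (SCR/thyristor)
rather than a mathematical reset rule. The membrane node obeys

```
C1 dV_mem/dt = I_in(t) − V_mem/R_leak − p · I_scr(p · V_mem)
```

with polarity `p = ±1` (the mirrored, inhibitory topology is a sign
convention, not a separate netlist). The SCR is phenomenological — two
linear resistive branches plus a forward drop and an explicit state bit:

* blocking: `I = V_ak / R_off`; switches on when
  `V_ak ≥ V_th(g) = clamp(V_th0 − α_gate·g, V_th_min, V_th0)`;
* conducting: `I = max(0, V_ak − V_on) / R_on`; switches off when
  `I ≤ I_hold`;
* reverse bias blocks (diode-like) through `R_off` in both states.

This is deliberately not a junction-physics (Gummel–Poon) model: the
circuit behaviors depend on the device only through `V_th`, `I_hold`, the
two resistances and the forward drop. The whole gate network is collapsed
to one scalar "gate drive" voltage mapped linearly (with clamping) onto
the threshold via `α_gate`; the resistor-divider detail of a physical gate
circuit is absorbed into that one coefficient. The two-transistor axon
stage is a memoryless comparator on the anode current (`V_pulse` iff
`I_ak ≥ I_trigger`): it shapes the output pulse and adds no dynamics.

Consequences of the device model worth knowing:

* The reset level is not zero: a conducting episode ends at
  `V_reset = V_on + I_hold·R_on`. Any threshold floor (`V_th_min`, or a
  feedback-lowered threshold) must stay above `V_reset`, otherwise the
  device re-fires immediately on turn-off; the integrator detects this as
  chattering and aborts with a diagnostic rather than silently coarsening.
* Sustained drive must stay below `I_hold` (for the standard soma) or the
  input current alone can hold the SCR on. The `mixed` scenario uses a
  fast-recovery parameterization (`I_hold = 30 µA`, `R_on = 10 kΩ`)
  precisely so its onset surge cannot latch the device.

## Circuit variants

| variant | extra states | mechanism |
|---|---|---|
| `base` | — | current source straight into the membrane node |
| `phasic` | `v_cin` | series `R_in`–`C_in` differentiator; only input *changes* pass |
| `mixed` | `v_cin` | differentiator plus a parallel DC path `R_dc` |
| `adaptive` | `w_fb` | per-spike jump `β_fb`, exponential decay `R_fb·C_fb`; acts as gate drive (threshold lowering) and/or membrane shunt `g_shunt·w_fb` |
| `inhibitory` | — | base topology with `p = −1` |

For capacitively-coupled variants the current-source amplitude is
converted to a Thevenin source voltage `V_src = u(t)·R_in`, so the
stimulus amplitude keeps its meaning as the current delivered into a
discharged circuit.

Two design points were genuinely open:

* **Adaptation.** Threshold lowering by spike-triggered gate feedback
  *shortens* interspike intervals in an LIF, so it cannot by itself produce
  spike-frequency adaptation. The feedback variable therefore also (or
  instead) accumulates a membrane shunt conductance `g_shunt·w_fb`, the
  standard adaptation-current idiom; the shipped adaptation scenario uses
  the shunt only (`α_gate = 0`).
* **Class 2 excitability.** A steady rate set by a DC path is always
  log-divergent at threshold (class 1), so no parameterization of the
  `mixed` variant yields a genuine rate discontinuity. The shipped class-2
  scenario instead uses the gate feedback as a fast positive loop: once the
  first spike lowers the threshold (to a floor above the reset level), the
  neuron continues at a finite minimum rate, giving a bistable onset and a
  jump in the f-I curve.
* **Rebound spike.** Defined here as a spike *after* the offset of a
  hyperpolarizing pulse with none during it. A mirrored-polarity neuron
  fires during negative drive, not after it, so the rebound scenario uses
  the differentiator variant: the release edge of the negative pulse
  injects a depolarizing surge through `C_in`.

## Numerics

* Between events the system is a smooth ODE, stiff while conducting
  (`R_on·C1` is typically 10³–10⁵ times shorter than `R_leak·C1`);
  it is advanced with `scipy.integrate.solve_ivp` (LSODA,
  `rtol = 1e-9`, `atol = 1e-12`, `max_step = dt_max`, dense output).
* The active event function — `V_ak − V_th(g)` while blocking,
  `I_ak − I_hold` while conducting — is a terminal event; its root is
  refined to machine precision (the documented guarantee is `event_tol`,
  default 1 ns). Integration also splits at stimulus breakpoints so the
  solver never steps across an input discontinuity.
* An event condition already satisfied at mode entry fires with zero
  dwell; more than 25 consecutive dwellings shorter than `min_dwell`
  (default 0.1 µs) abort as chattering.
* Traces sample a uniform grid (default 1 µs) plus the exact event times,
  each stored twice with the pre/post discrete state. CSV uses `%.17g`, so
  files round-trip IEEE doubles bit-exactly.
* There is no randomness anywhere; reruns are bit-identical.
* An independent fixed-step reference integrator (explicit Euler or RK4,
  with sign-change bisection on the linear interpolant for event location)
  cross-validates the event engine; on the tonic scenario they agree on
  the spike count exactly and on `V_mem` to well under 1 % of `V_th0`.
  The tonic scenario uses a conducting time constant of 100 µs
  (`R_on = 100 kΩ`) so that a plain fixed-step method resolves the
  discharge edge and this comparison is meaningful.

## Parameters and units

All quantities are SI. Canonical defaults (engineering choices on the
millisecond scale; every scenario overrides what it needs):
`C1 = 1 nF`, `R_leak = 1 MΩ` (τ = 1 ms), `V_th0 = 2 V`, `V_th_min = 0.5 V`,
`I_hold = 10 µA`, `R_off = 10 MΩ`, `R_on` 10 Ω (device default) to 100 kΩ
(scenario values chosen for well-resolved pulses), `V_on = 0.8 V`,
`V_pulse = 5 V`. The rheobase of the base circuit is
`V_th0·(1/R_leak + 1/R_off) ≈ 2.2 µA`; most driven scenarios use 4.4 µA
(twice rheobase). Classifier rule thresholds (spike threshold
`v_half = V_pulse/2`, refractory merge window, burst `isi_intra/inter`,
`f_eps`/`f_jump` for the excitability classes) live in each scenario
config, scaled to its time constant.

## Scenario battery

Twelve JSON fixtures, one per behavior, each declaring variant, component
values, stimulus, rule thresholds and the expected label. Component values
are this package's own choices: they were selected (by simulation) to
place each scenario robustly inside its behavioral regime, e.g. the phasic
scenario's `C_in` delivers the onset charge for exactly one spike, the
bursting scenario's smaller `C_in` with a stronger step for three, and the
latency scenario drives at 1.02× rheobase so the first spike arrives after
more than three tonic reference latencies. Multi-run behaviors bundle
their stimulus sets: integrator (paired pulses at 0.1 ms vs 4 ms gap),
accommodation (6 ms ramp vs step of the same 8 µA amplitude), class 1/2
(step-amplitude sweeps of 8 and 6 points). Problem sizes — 8–30 ms of
model time per run at a 1 ms membrane constant — give every scenario tens
of firing cycles where relevant; the full battery runs in a few seconds of
wall time.

## What the battery does and does not show

The scenarios are synthetic study conditions: ideal current sources,
noiseless components, a piecewise-linear device. Passing shows that the
hybrid model of this circuit family produces the twelve qualitative firing
patterns and that the engine integrates it accurately (closed-form LIF
checks to < 2 %, independent-integrator agreement, hysteresis and
determinism invariants). It does not show component-tolerance robustness,
temperature effects, dV/dt-induced false turn-on, junction-level switching
transients, or behavior of physically interconnected multi-neuron
networks — all outside the model. Time constants are circuit-scale
(milliseconds), 10³–10⁴ faster than biology; no biological calibration is
attempted. The behavior predicates are this package's conventions for
making figure-defined patterns testable (e.g. the burst/mixed split and
the 3× latency criterion); other reasonable thresholds would classify
edge cases differently.
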