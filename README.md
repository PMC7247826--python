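# ucnsim

A hybrid dynamical-system simulator for the **ultra-compact neuron (UCN)**:
a leaky integrate-and-fire (LIF) circuit whose firing element is a
hysteretic threshold-switching device — a silicon controlled rectifier
(SCR, thyristor). The package is aimed at neuromorphic-circuit and
computational-neuroscience work that needs a fast, fully deterministic
software twin of this circuit family: it ships the circuit variants, the
stimulus generators, an event-accurate integrator, spike-train analytics, a
behavior classifier, and a 12-scenario battery reproducing twelve
biologically relevant spiking behaviors from the Izhikevich catalogue.

## The model

The soma is one capacitor, one resistor and the SCR:

```
C1 dV_mem/dt = I_in(t) − V_mem / R_leak − I_scr(V_mem)
```

The SCR has two resistive states. Blocking, it is a high resistance
`R_off`; it switches on when the anode–cathode voltage reaches the
breakover threshold `V_th(g) = clamp(V_th0 − α_gate · g, V_th_min, V_th0)`
(`g` is the gate-drive voltage). Conducting, it is `R_on` in series with a
forward drop `V_on`, and it switches back off only when its current falls
below the holding current `I_hold`. The voltage-driven turn-on and
current-driven turn-off make the I–V characteristic hysteretic
(memristive), and that hysteresis is what produces integrate → fire →
reset: the capacitor charges, the SCR fires, dumps the charge, and recovers
once the discharge current falls below `I_hold`. An idealized axon stage
(a comparator on the anode current) emits the rectangular output pulse
`V_out`.

Simulation is event-driven: between switchings the circuit is a smooth
(stiff, when conducting) ODE advanced with an adaptive stiff-capable
stepper; the threshold and holding-current crossings are terminal events
located to machine precision, and the discrete transition is applied
exactly once per event. A brute-force fixed-step reference integrator
(explicit Euler / RK4) is included for cross-validation.

Circuit variants (all sharing the soma): `base` (current step in),
`phasic` (RC differentiator input), `mixed` (differentiator + DC path),
`adaptive` (spike-triggered gate feedback and/or membrane shunt) and
`inhibitory` (mirrored polarity, fires on negative input). Together they
reproduce: tonic spiking, phasic spiking, phasic bursting, mixed
(burst-then-spiking), spike-frequency adaptation, class 1 and class 2
excitability, spike latency, integrator, accommodation, rebound spike, and
inhibition-induced spiking.

## Worked example

```python
import ucnsim as u

circuit = u.CircuitParams(c1=1e-9, r_leak=1e6)          # tau = 1 ms
scr = u.SCRParams(v_th0=2.0, i_hold=5e-6, r_on=1e5, v_on=0.8)
axon = u.AxonParams(i_trigger=6e-6, v_pulse=5.0)
neuron = u.build_circuit("base", circuit, scr, axon)

stim = u.make_stimulus("step", t_on=1e-3, amplitude=4.4e-6)   # ~2x rheobase
trace = u.simulate(neuron, stim, t_end=9e-3)

spikes = u.detect_spikes(trace, v_half=2.5, t_refractory=5e-5)
isis = u.interspike_intervals(spikes)
print(f"spikes: {len(spikes)}")
print(f"first spike latency: {u.latency(spikes, 1e-3)*1e3:.3f} ms")
print(f"mean ISI: {isis.mean()*1e3:.3f} ms  (adaptation index {u.adaptation_index(isis):+.3f})")
print("label:", u.classify_behavior(trace, stim, u.ClassifierRules(
    t_refractory=5e-5, isi_intra=1e-4, isi_inter=2e-4)))
```

prints

```
spikes: 18
first spike latency: 0.630 ms
mean ISI: 0.420 ms  (adaptation index -0.000)
label: tonic_spiking
```

A 4.4 µA step is roughly twice the rheobase (the threshold drive
`V_th0 / R_leak ≈ 2.2 µA` including the blocking leak), so the neuron fires
a regular ~2.4 kHz train: 18 spikes with essentially identical interspike
intervals (adaptation index ≈ 0) — tonic spiking. The latency is the RC
charge-up time from rest to threshold, `τ ln(A/(A − V_th)) ≈ 0.63 ms`.

## Command line

```sh
ucnsim list                         # the 12 shipped scenarios
ucnsim battery --out out/           # run all, write traces + report.json
ucnsim run src/ucnsim/scenarios/a_tonic_spiking.json --out out/
ucnsim plot out/a_tonic_spiking.csv # stacked I_IN / V_MEM / V_OUT panels
```

`ucnsim battery` exits nonzero iff any scenario's observed label differs
from its expected one. Traces are plain CSV
(`t,u,v_mem,v_out,conducting`, SI units, event times duplicated with the
pre/post switching state, floats at 17 significant digits so the files
round-trip bit-exactly).

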